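"""Exception hierarchy shared across the package."""


class Lesion2ScoreError(Exception):
    """Base class for all package errors."""


class GridError(Lesion2ScoreError):
    """Volume shape or voxel ordering does not match the 61x73x61 grid."""


class ValidationError(Lesion2ScoreError):
    """Input content violates a contract (non-binary mask, NaNs, ...)."""


class ManifestError(Lesion2ScoreError):
    """Cohort manifest is malformed (duplicate ids, missing columns, ...)."""


class ConfigurationError(Lesion2ScoreError):
    """Invalid or infeasible configuration value."""


class CoordinateError(Lesion2ScoreError):
    """Voxel coordinate outside the grid."""


class CapacityError(Lesion2ScoreError):
    """Requested lesion volume cannot fit the grid."""


class DegeneracyError(Lesion2ScoreError):
    """Operation undefined on degenerate input (empty mask, zero variance, ...)."""


class StateError(Lesion2ScoreError):
    """Object used before it reached the required state (e.g. untrained model)."""


class FoldError(Lesion2ScoreError):
    """Model training failed inside a cross-validation fold."""

    def __init__(self, fold_index: int, message: str):
        self.fold_index = fold_index
        super().__init__(f"fold {fold_index}: {message}")
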