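"""Lesion volumes, cohort manifests, and the fixed voxel vectorization.

All volumes in the package live on a single 3 mm isotropic grid of shape
``(61, 73, 61)`` (a standard 3 mm down-sampling of MNI space).  Axis 0 runs
left-to-right (lower indices = left hemisphere), axis 1 posterior-to-anterior,
axis 2 inferior-to-superior.  ``flatten`` uses C order (last axis fastest);
this single ordering is used everywhere a volume becomes a feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import GridError, ManifestError, ValidationError

#: Fixed grid shape for every lesion volume (3 mm isovoxel MNI-like space).
GRID_SHAPE = (61, 73, 61)
#: Number of voxels in the grid: 61 * 73 * 61.
N_VOXELS = int(np.prod(GRID_SHAPE))
#: Voxel edge length in millimetres.
VOXEL_SIZE_MM = 3.0
#: First-axis index at which the right hemisphere starts (midline column 30
#: belongs to neither side; centroids there are labelled 'L' by convention).
MIDLINE_INDEX = GRID_SHAPE[0] // 2

#: RAS+ affine mapping voxel indices to millimetres, 3 mm isotropic.
DEFAULT_AFFINE = np.array(
    [
        [3.0, 0.0, 0.0, -90.0],
        [0.0, 3.0, 0.0, -108.0],
        [0.0, 0.0, 3.0, -90.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)

#: Tolerance for snapping near-binary voxel values on read.
BINARY_TOLERANCE = 1e-6

MANIFEST_COLUMNS = [
    "patient_id",
    "score",
    "score_followup",
    "hemisphere",
    "lesion_volume_voxels",
]


@dataclass
class LesionImage:
    """A binary lesion mask on the fixed grid.

    Parameters
    ----------
    voxels : ndarray of shape (61, 73, 61)
        Binary mask; 1 marks lesioned tissue.
    patient_id : str, optional
        Identifier linking the image to a manifest row.
    space_label : str
        Name of the common reference frame the mask lives in.
    """

    voxels: np.ndarray
    patient_id: str | None = None
    space_label: str = "mni-3mm-61x73x61"

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.shape != GRID_SHAPE:
            raise GridError(
                f"lesion mask must have shape {GRID_SHAPE}, got {arr.shape}"
            )
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError("lesion mask must be binary (values in {0, 1})")
        self.voxels = arr.astype(np.uint8)

    @property
    def volume(self) -> int:
        """Lesion volume in voxels."""
        return int(self.voxels.sum())

    def flatten(self) -> np.ndarray:
        return flatten(self)


@dataclass
class CohortManifest:
    """Per-patient scores and metadata, one row per patient.

    Wraps a DataFrame with columns ``patient_id, score, score_followup,
    hemisphere, lesion_volume_voxels``.  ``score_followup`` may be NaN for
    patients without 3-month retest data.
    """

    records: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in ("patient_id", "score", "hemisphere") if c not in df.columns]
        if missing:
            raise ManifestError(f"manifest missing required columns: {missing}")
        if df["patient_id"].duplicated().any():
            dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
            raise ManifestError(f"duplicate patient ids: {dupes}")
        if not df["hemisphere"].isin(["L", "R"]).all():
            raise ManifestError("hemisphere must be 'L' or 'R' for every patient")
        if not np.isfinite(df["score"].to_numpy(dtype=float)).all():
            raise ManifestError("scores must be finite numbers")
        if "score_followup" not in df.columns:
            df = df.assign(score_followup=np.nan)
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def patient_ids(self) -> list[str]:
        return self.records["patient_id"].tolist()

    @property
    def scores(self) -> np.ndarray:
        return self.records["score"].to_numpy(dtype=float)

    @property
    def followup_scores(self) -> np.ndarray:
        """Follow-up scores with NaN where absent."""
        return self.records["score_followup"].to_numpy(dtype=float)

    @property
    def hemispheres(self) -> np.ndarray:
        return self.records["hemisphere"].to_numpy()

    def subset(self, index: np.ndarray) -> "CohortManifest":
        return CohortManifest(
            self.records.iloc[np.asarray(index)].reset_index(drop=True),
            provenance=self.provenance,
        )


def write_mask(image: LesionImage, path) -> None:
    """Write a lesion mask as NIfTI-1 with the 3 mm isotropic affine."""
    img = nib.Nifti1Image(image.voxels.astype(np.uint8), DEFAULT_AFFINE)
    nib.save(img, str(path))


def read_mask(path, patient_id: str | None = None) -> LesionImage:
    """Read and validate a NIfTI lesion mask.

    Values within ``BINARY_TOLERANCE`` of 0 or 1 are snapped; anything else
    raises :class:`ValidationError`.  Shape must be exactly ``GRID_SHAPE``.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.shape != GRID_SHAPE:
        raise GridError(f"expected shape {GRID_SHAPE}, got {data.shape} in {path}")
    rounded = np.rint(data)
    if np.abs(data - rounded).max() > BINARY_TOLERANCE or not np.isin(rounded, (0, 1)).all():
        raise ValidationError(f"mask {path} contains non-binary values")
    return LesionImage(rounded.astype(np.uint8), patient_id=patient_id)


def flatten(image: LesionImage | np.ndarray) -> np.ndarray:
    """Vectorize a grid volume in C order (last axis fastest); length 271,633."""
    arr = image.voxels if isinstance(image, LesionImage) else np.asarray(image)
    if arr.shape != GRID_SHAPE:
        raise GridError(f"expected shape {GRID_SHAPE}, got {arr.shape}")
    return arr.reshape(-1)


def unflatten(vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`flatten`."""
    vec = np.asarray(vector)
    if vec.shape != (N_VOXELS,):
        raise GridError(f"expected a length-{N_VOXELS} vector, got shape {vec.shape}")
    return vec.reshape(GRID_SHAPE)


def stack_flat(images: list[LesionImage], dtype=np.float32) -> np.ndarray:
    """Stack a cohort into an (n, 271633) design matrix with the fixed ordering."""
    return np.stack([flatten(im).astype(dtype) for im in images])


def write_manifest(manifest: CohortManifest, path) -> None:
    """Write the manifest as a UTF-8 CSV with a header row."""
    df = manifest.records
    cols = [c for c in MANIFEST_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def read_manifest(path) -> CohortManifest:
    """Read and validate a cohort manifest CSV.

    Empty ``score_followup`` cells are preserved as missing (NaN), never 0.
    """
    try:
        df = pd.read_csv(path, dtype={"patient_id": str})
    except (ValueError, OSError) as exc:
        raise ManifestError(f"cannot parse manifest {path}: {exc}") from exc
    required = {"patient_id", "score", "hemisphere"}
    if not required.issubset(df.columns):
        raise ManifestError(
            f"manifest {path} missing columns {sorted(required - set(df.columns))}"
        )
    for col in ("score", "score_followup"):
        if col in df.columns and not pd.api.types.is_numeric_dtype(df[col]):
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise ManifestError(f"unparsable values in column {col!r}") from exc
    if df["score"].isna().any():
        raise ManifestError("missing acute scores in manifest")
    return CohortManifest(df, provenance=str(path))
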