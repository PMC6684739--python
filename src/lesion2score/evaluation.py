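"""Leave-one-out cross-validation harness, metrics, subgroups, comparisons.

Each of the n patients is predicted once, by a pipeline (PCA scope, lambda
search, model fit) that never saw that patient; pooled predictions are scored
with r^2 (squared Pearson correlation) and mean absolute error.

For the feature-based models (ridge, SVR, hybrid ridge input) the per-fold
PCA is evaluated through the cohort Gram matrix: the training-fold PCA basis
and the held-out projection are exact functions of Gram submatrices, and both
ridge and RBF-kernel SVR predictions are invariant to the orthonormal basis
choice, so this path is prediction-equivalent to explicitly refitting PCA on
the fold's voxel data (asserted in tests) at a tiny fraction of the cost.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnn import CNNConfig, SparseLesionPatch, fit_cnn
from .exceptions import (
    ConfigurationError,
    DegeneracyError,
    FoldError,
    ValidationError,
)
from .hybrid import fit_hybrid
from .imaging import N_VOXELS, CohortManifest, stack_flat
from .pca import fit_pca, fold_pca_features, gram_matrix
from .ridge import DEFAULT_LAMBDA_GRID, fit_ridge, select_lambda_loo
from .svr import SVRConfig, fit_svr, fit_svr_precomputed

# ---------------------------------------------------------------------------
# Model specifications


@dataclass(frozen=True)
class RidgeSpec:
    """PCA + ridge regression with per-fold LOO lambda search."""

    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    label: str = "pca+rr"


@dataclass(frozen=True)
class SVRSpec:
    """Epsilon-SVR (C=50, eps=0.1, gamma = 1/n input features).

    ``input_mode="raw"`` (default) trains on the raw flattened images via a
    precomputed RBF kernel (gamma = 1/271633, which keeps the kernel
    informative); ``"pca"`` trains on the fold's PCA features (gamma = 1/k).
    """

    config: SVRConfig = field(default_factory=SVRConfig)
    input_mode: str = "raw"
    label: str = "svr"

    def __post_init__(self) -> None:
        if self.input_mode not in ("raw", "pca"):
            raise ConfigurationError("SVR input_mode must be 'raw' or 'pca'")


@dataclass(frozen=True)
class CNNSpec:
    """3D CNN trained per fold on the raw masks."""

    config: CNNConfig = field(default_factory=CNNConfig)
    label: str = "cnn"


@dataclass(frozen=True)
class HybridSpec:
    """Ridge on [PCA | CNN fully-connected] features; shares the fold CNN."""

    config: CNNConfig = field(default_factory=CNNConfig)
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    label: str = "hybrid"


def spec_from_name(name: str, cnn_config: CNNConfig | None = None):
    table = {
        "ridge": RidgeSpec(),
        "pca+rr": RidgeSpec(),
        "rr": RidgeSpec(),
        "svr": SVRSpec(),
        "cnn": CNNSpec(config=cnn_config or CNNConfig()),
        "hybrid": HybridSpec(config=cnn_config or CNNConfig()),
    }
    if name not in table:
        raise ConfigurationError(f"unknown model {name!r}; choose from {sorted(table)}")
    return table[name]


# ---------------------------------------------------------------------------
# Metrics


def r_squared(actual, predicted) -> float:
    """Square of the Pearson correlation between actual and predicted scores.

    Returns 0.0 when either vector is constant (degenerate-correlation
    convention; flagged separately in :class:`EvalResult`).
    """
    a = np.asarray(actual, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if a.shape != p.shape or a.ndim != 1:
        raise ValidationError(f"incompatible shapes {a.shape} vs {p.shape}")
    if a.std() == 0 or p.std() == 0:
        return 0.0
    r = np.corrcoef(a, p)[0, 1]
    return float(r**2)


def mae(actual, predicted) -> float:
    """Mean absolute error between actual and predicted scores."""
    a = np.asarray(actual, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if a.shape != p.shape:
        raise ValidationError(f"incompatible shapes {a.shape} vs {p.shape}")
    return float(np.mean(np.abs(a - p)))


@dataclass
class EvalResult:
    """Pooled per-patient predictions of one model plus summary metrics."""

    predictions: pd.DataFrame  # columns: patient_id, actual, predicted
    model_label: str
    subgroup_label: str = "all"
    extras: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.predictions)

    @property
    def actual(self) -> np.ndarray:
        return self.predictions["actual"].to_numpy()

    @property
    def predicted(self) -> np.ndarray:
        return self.predictions["predicted"].to_numpy()

    @property
    def degenerate(self) -> bool:
        """True when either pooled vector is constant (r^2 reported as 0)."""
        return bool(self.actual.std() == 0 or self.predicted.std() == 0)

    @property
    def r_squared(self) -> float:
        return r_squared(self.actual, self.predicted)

    @property
    def mae(self) -> float:
        return mae(self.actual, self.predicted)

    def metrics(self) -> dict:
        return {
            "model": self.model_label,
            "subgroup": self.subgroup_label,
            "n": self.n,
            "r_squared": self.r_squared,
            "mae": self.mae,
            "degenerate": self.degenerate,
        }

    def summary(self) -> str:
        m = self.metrics()
        flag = "  (degenerate: constant predictions)" if m["degenerate"] else ""
        return (
            f"{self.model_label} [{self.subgroup_label}] n={m['n']}  "
            f"r2={m['r_squared']:.3f}  MAE={m['mae']:.3f}{flag}"
        )


# ---------------------------------------------------------------------------
# LOOCV harness


def _fold_seed(master_seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([master_seed, fold]).generate_state(1)[0] % (2**31))


def loocv(
    images,
    manifest: CohortManifest,
    specs,
    master_seed: int = 0,
    variance_threshold: float = 0.95,
    pca_scope: str = "fold",
    score_column: str = "score",
    gram: np.ndarray | None = None,
) -> dict[str, EvalResult]:
    """Run leave-one-out cross-validation for one or more model specs.

    Expensive per-fold artifacts are shared across specs: the fold PCA
    features feed ridge, SVR and the hybrid, and a fold CNN trained once
    serves both the CNN spec and the hybrid's feature extractor when their
    configs coincide.

    ``pca_scope`` is ``"fold"`` (PCA refit inside each training fold; no
    leakage) or ``"whole-dataset"`` (PCA fit once on all images, emulating the
    plausible original pipeline).

    ``gram`` may carry the cohort Gram matrix (``gram_matrix(stack_flat(images))``)
    precomputed by the caller; useful when evaluating the same images against
    many score vectors (e.g. permutation nulls).
    """
    if isinstance(specs, (RidgeSpec, SVRSpec, CNNSpec, HybridSpec)):
        specs = [specs]
    specs = list(specs)
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ConfigurationError(f"duplicate model labels: {labels}")
    if pca_scope not in ("fold", "whole-dataset"):
        raise ConfigurationError("pca_scope must be 'fold' or 'whole-dataset'")

    n = len(images)
    if n < 3:
        raise ValidationError("LOOCV needs at least 3 patients")
    if len(manifest) != n:
        raise ValidationError("manifest and image counts differ")
    if score_column == "score":
        y = manifest.scores
    elif score_column in ("followup", "score_followup"):
        y = manifest.followup_scores
        if np.isnan(y).any():
            raise ConfigurationError(
                "follow-up LOOCV requires follow-up scores for every patient; "
                "restrict the cohort first"
            )
    else:
        raise ConfigurationError(f"unknown score column {score_column!r}")

    need_features = any(
        isinstance(s, (RidgeSpec, HybridSpec))
        or (isinstance(s, SVRSpec) and s.input_mode == "pca")
        for s in specs
    )
    need_cnn = any(isinstance(s, (CNNSpec, HybridSpec)) for s in specs)

    raw_specs = [s for s in specs if isinstance(s, SVRSpec) and s.input_mode == "raw"]
    G = None
    Z_whole = None
    K_raw = None
    if need_features or raw_specs:
        if gram is not None:
            if gram.shape != (n, n):
                raise ValidationError(f"gram matrix shape {gram.shape} != ({n}, {n})")
            G = np.asarray(gram, dtype=np.float64)
        else:
            G = gram_matrix(stack_flat(images))
        if need_features and pca_scope == "whole-dataset":
            X = stack_flat(images).astype(np.float64)
            model = fit_pca(X, variance_threshold)
            Z_whole = model.transform(X).values
        if raw_specs:
            # Full-cohort RBF kernel on raw voxels, from the Gram matrix.
            gamma = raw_specs[0].config.resolve_gamma(N_VOXELS)
            v = np.diag(G)
            K_raw = np.exp(-gamma * (v[:, None] + v[None, :] - 2 * G))

    patches = None
    if need_cnn:
        patches = [SparseLesionPatch.from_image(im) for im in images]

    preds = {s.label: np.empty(n) for s in specs}
    lambdas = {s.label: [] for s in specs if isinstance(s, (RidgeSpec, HybridSpec))}
    ks: list[int] = []

    for i in range(n):
        train = np.setdiff1d(np.arange(n), [i])
        y_tr = y[train]
        try:
            Z_tr = Z_te = None
            if need_features:
                if pca_scope == "fold":
                    Z_tr, Z_te, k = fold_pca_features(
                        G, train, np.array([i]), variance_threshold
                    )
                else:
                    Z_tr, Z_te, k = Z_whole[train], Z_whole[[i]], Z_whole.shape[1]
                ks.append(k)

            cnn_cache: dict = {}

            def fold_cnn(config: CNNConfig):
                key = config
                if key not in cnn_cache:
                    cfg = dataclasses.replace(config, seed=_fold_seed(master_seed, i))
                    cnn_cache[key] = fit_cnn(
                        [images[j] for j in train],
                        y_tr,
                        cfg,
                        patches=[patches[j] for j in train],
                    )
                return cnn_cache[key]

            for s in specs:
                if isinstance(s, RidgeSpec):
                    lam = select_lambda_loo(Z_tr, y_tr, s.lambda_grid)
                    res = fit_ridge(Z_tr, y_tr, lam)
                    preds[s.label][i] = res.predict(Z_te)[0]
                    lambdas[s.label].append(lam)
                elif isinstance(s, SVRSpec):
                    if s.input_mode == "raw":
                        est = fit_svr_precomputed(
                            K_raw[np.ix_(train, train)], y_tr, s.config
                        )
                        preds[s.label][i] = est.predict(K_raw[np.ix_([i], train)])[0]
                    else:
                        res = fit_svr(Z_tr, y_tr, s.config)
                        preds[s.label][i] = res.predict(Z_te)[0]
                elif isinstance(s, CNNSpec):
                    res = fold_cnn(s.config)
                    preds[s.label][i] = res.predict([images[i]])[0]
                elif isinstance(s, HybridSpec):
                    cnn_res = fold_cnn(s.config)
                    F_tr = cnn_res.features([images[j] for j in train])
                    F_te = cnn_res.features([images[i]])
                    hyb = fit_hybrid(Z_tr, F_tr, y_tr, s.lambda_grid)
                    preds[s.label][i] = hyb.predict(Z_te, F_te)[0]
                    lambdas[s.label].append(hyb.lam)
        except Exception as exc:  # noqa: BLE001 - annotate with the fold index
            if isinstance(exc, FoldError):
                raise
            raise FoldError(i, str(exc)) from exc

    out = {}
    for s in specs:
        extras: dict = {"master_seed": master_seed, "pca_scope": pca_scope}
        if s.label in lambdas:
            extras["fold_lambdas"] = lambdas[s.label]
        if ks:
            extras["pca_components"] = ks
        out[s.label] = EvalResult(
            predictions=pd.DataFrame(
                {
                    "patient_id": manifest.patient_ids,
                    "actual": y,
                    "predicted": preds[s.label],
                }
            ),
            model_label=s.label,
            extras=extras,
        )
    return out


# ---------------------------------------------------------------------------
# Subgroups and model comparison

SUBGROUP_FILTERS = ("left_hemisphere", "deficit_only", "no_deficit")


def subgroup_eval(result: EvalResult, manifest: CohortManifest, filter_name: str) -> EvalResult:
    """Recompute metrics on a subgroup of the pooled predictions (no retrain).

    ``deficit_only`` keeps score < 0 (strict), ``no_deficit`` keeps score >= 0,
    ``left_hemisphere`` keeps hemisphere == 'L'.
    """
    if filter_name not in SUBGROUP_FILTERS:
        raise ConfigurationError(
            f"unknown subgroup {filter_name!r}; choose from {SUBGROUP_FILTERS}"
        )
    df = result.predictions.merge(
        manifest.records[["patient_id", "hemisphere"]], on="patient_id", how="left"
    )
    if filter_name == "left_hemisphere":
        keep = df["hemisphere"] == "L"
    elif filter_name == "deficit_only":
        keep = df["actual"] < 0
    else:
        keep = df["actual"] >= 0
    sub = df.loc[keep, ["patient_id", "actual", "predicted"]].reset_index(drop=True)
    if len(sub) < 3:
        raise DegeneracyError(
            f"subgroup {filter_name!r} has only {len(sub)} patients (< 3)"
        )
    return EvalResult(
        predictions=sub,
        model_label=result.model_label,
        subgroup_label=filter_name,
        extras=dict(result.extras),
    )


def _bootstrap_r2(a: np.ndarray, p: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Vectorized r^2 over bootstrap resamples (rows of idx); constant -> 0."""
    xa, xp = a[idx], p[idx]
    xa = xa - xa.mean(axis=1, keepdims=True)
    xp = xp - xp.mean(axis=1, keepdims=True)
    num = (xa * xp).sum(axis=1)
    den = np.sqrt((xa**2).sum(axis=1) * (xp**2).sum(axis=1))
    out = np.zeros(idx.shape[0])
    ok = den > 0
    out[ok] = (num[ok] / den[ok]) ** 2
    return out


def compare_models(
    result_a: EvalResult,
    result_b: EvalResult,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Paired patient-level bootstrap test for a difference in r^2.

    Returns (delta_r2 = r2_A - r2_B, two-sided p for delta = 0).  Patients are
    resampled with replacement jointly for both models; the p-value uses the
    add-one rule and is capped at 1.
    """
    ids_a = result_a.predictions["patient_id"].tolist()
    ids_b = result_b.predictions["patient_id"].tolist()
    if set(ids_a) != set(ids_b):
        raise ValidationError("results cover different patient sets")
    b = result_b.predictions.set_index("patient_id").loc[ids_a]
    a_act = result_a.actual
    a_pred = result_a.predicted
    b_pred = b["predicted"].to_numpy()

    delta = r_squared(a_act, a_pred) - r_squared(a_act, b_pred)
    rng = np.random.default_rng(seed)
    n = len(ids_a)
    idx = rng.integers(0, n, size=(n_boot, n))
    d = _bootstrap_r2(a_act, a_pred, idx) - _bootstrap_r2(a_act, b_pred, idx)
    p_lo = (1 + np.sum(d <= 0)) / (n_boot + 1)
    p_hi = (1 + np.sum(d >= 0)) / (n_boot + 1)
    p = min(1.0, 2.0 * min(p_lo, p_hi))
    return float(delta), float(p)
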