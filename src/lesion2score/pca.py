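"""PCA of flattened lesion masks via (Gram-based) singular value decomposition.

With ~100 samples of ~270k voxels the data matrix is extremely wide, so the
decomposition is computed from the n x n Gram matrix of the centred rows; this
is algebraically exact (identical to a full SVD of the centred matrix, up to
component sign) and costs O(n^2 p) once instead of O(n p^2).

The module also exposes the Gram-submatrix fast path used by the LOOCV
harness: once the cohort-wide Gram matrix of the *uncentred* rows is computed,
the PCA of any training fold and the projection of the held-out image are both
available without touching voxel space again.  Ridge and RBF-kernel SVR
predictions depend on the fitted subspace only through inner products, so the
fast path is prediction-equivalent to refitting the PCA explicitly per fold
(asserted in the tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegeneracyError, GridError, ValidationError

#: Relative eigenvalue floor below which directions are treated as null space.
_EIG_RTOL = 1e-10


@dataclass
class PCAModel:
    """Fitted PCA basis for lesion feature extraction.

    Attributes
    ----------
    mean_vector : (p,) ndarray
        Training mean per voxel.
    components : (k, p) ndarray
        Retained orthonormal directions, variance-ordered.
    explained_variance_ratio : (r,) ndarray
        Ratios of *all* r candidate (nonzero-variance) components; sums to 1.
    k : int
        Retained component count: the smallest k whose cumulative ratio
        reaches ``variance_threshold``.
    variance_threshold : float
    """

    mean_vector: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray
    k: int
    variance_threshold: float

    def transform(self, image: np.ndarray) -> np.ndarray:
        return transform(self, image)

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            mean_vector=self.mean_vector,
            components=self.components,
            explained_variance_ratio=self.explained_variance_ratio,
            k=self.k,
            variance_threshold=self.variance_threshold,
        )

    @classmethod
    def load(cls, path) -> "PCAModel":
        with np.load(path) as z:
            return cls(
                mean_vector=z["mean_vector"],
                components=z["components"],
                explained_variance_ratio=z["explained_variance_ratio"],
                k=int(z["k"]),
                variance_threshold=float(z["variance_threshold"]),
            )


@dataclass
class FeatureVector:
    """Projection coordinates of one image onto a PCAModel's components."""

    values: np.ndarray
    source_id: str | None = None


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Make each component's largest-magnitude loading positive (determinism)."""
    idx = np.argmax(np.abs(components), axis=1)
    signs = np.sign(components[np.arange(components.shape[0]), idx])
    signs[signs == 0] = 1.0
    return components * signs[:, None]


def n_components_for_threshold(ratios: np.ndarray, threshold: float) -> int:
    """Smallest k with cumulative explained-variance ratio >= threshold."""
    cum = np.cumsum(ratios)
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)


def fit_pca(images: np.ndarray, variance_threshold: float = 0.95) -> PCAModel:
    """Fit PCA on an (n, p) matrix of flattened masks.

    Components are computed from the eigendecomposition of the centred Gram
    matrix and mapped back to voxel space; equivalent to a direct SVD of the
    centred matrix.  Raises DegeneracyError when all rows are identical.
    """
    X = np.asarray(images, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("fit_pca needs an (n >= 2, p) matrix")
    if not 0 < variance_threshold <= 1:
        raise ValidationError("variance_threshold must be in (0, 1]")
    n = X.shape[0]
    mean = X.mean(axis=0)
    Xc = X - mean
    G = Xc @ Xc.T
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    total = eigval.sum()
    if total <= 0:
        raise DegeneracyError("all images identical: zero total variance")
    keep = eigval > _EIG_RTOL * eigval[0]
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    ratios = eigval / eigval.sum()
    k = n_components_for_threshold(ratios, variance_threshold)
    comps = (Xc.T @ (eigvec[:, :k] / np.sqrt(eigval[:k]))).T
    comps = _fix_signs(comps)
    return PCAModel(
        mean_vector=mean,
        components=comps,
        explained_variance_ratio=ratios,
        k=k,
        variance_threshold=variance_threshold,
    )


def transform(model: PCAModel, image: np.ndarray) -> FeatureVector:
    """Project one flattened mask (or a stack) onto the retained components."""
    x = np.asarray(image, dtype=np.float64)
    if x.shape[-1] != model.mean_vector.shape[0]:
        raise GridError(
            f"image length {x.shape[-1]} does not match model "
            f"({model.mean_vector.shape[0]})"
        )
    return FeatureVector((x - model.mean_vector) @ model.components.T)


# ---------------------------------------------------------------------------
# Gram-submatrix fast path for cross-validation


def gram_matrix(X: np.ndarray) -> np.ndarray:
    """Uncentred Gram matrix X @ X.T in float64, computed once per cohort."""
    Xf = np.asarray(X, dtype=np.float32)
    return (Xf @ Xf.T).astype(np.float64)


def fold_pca_features(
    G: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    variance_threshold: float = 0.95,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Training/test PCA features of one CV fold from the cohort Gram matrix.

    Returns ``(Z_train (m, k), Z_test (t, k), k)`` where the feature basis is
    the PCA of the *training rows only* (no leakage).  Features equal those of
    an explicitly refit PCA up to a fixed rotation/sign, which leaves ridge
    and RBF-SVR predictions unchanged.
    """
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    m = train_idx.size
    if m < 2:
        raise ValidationError("fold needs at least two training samples")
    Gtt = G[np.ix_(train_idx, train_idx)]
    row_mean = Gtt.mean(axis=1)
    all_mean = Gtt.mean()
    Gc = Gtt - row_mean[:, None] - row_mean[None, :] + all_mean
    Gc = 0.5 * (Gc + Gc.T)
    eigval, eigvec = np.linalg.eigh(Gc)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval[0] <= 0:
        raise DegeneracyError("fold has zero variance")
    keep = eigval > _EIG_RTOL * eigval[0]
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    ratios = eigval / eigval.sum()
    k = n_components_for_threshold(ratios, variance_threshold)
    U = eigvec[:, :k]
    s = np.sqrt(eigval[:k])
    Z_train = U * s[None, :]
    # Centred cross inner products: (x_test - mu) @ Xc.T, from Gram entries.
    Gxt = G[np.ix_(test_idx, train_idx)]
    cross = Gxt - Gxt.mean(axis=1, keepdims=True) - row_mean[None, :] + all_mean
    Z_test = cross @ (U / s[None, :])
    return Z_train, np.atleast_2d(Z_test), k
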