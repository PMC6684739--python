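"""Hybrid model: ridge regression on concatenated PCA and CNN features.

The CNN's 500 fully-connected-layer activations are appended to the k PCA
projection coordinates and the combined design is fed to the same
lambda-selected ridge regression used by the PCA-only model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .ridge import DEFAULT_LAMBDA_GRID, RidgeResults, fit_ridge, select_lambda_loo


@dataclass
class HybridResults:
    """Fitted hybrid ridge over [PCA | CNN] features."""

    ridge: RidgeResults
    n_pca: int
    n_cnn: int

    def predict(self, pca_features, cnn_features) -> np.ndarray:
        X = _concat(pca_features, cnn_features, self.n_pca, self.n_cnn)
        return self.ridge.predict(X)

    @property
    def lam(self) -> float:
        return self.ridge.lam

    def summary(self) -> str:
        return "\n".join(
            [
                "Hybrid (PCA + CNN features -> ridge) results",
                "--------------------------------------------",
                f"PCA features:  {self.n_pca}",
                f"CNN features:  {self.n_cnn}",
                f"ridge input:   {self.n_pca + self.n_cnn}",
                f"lambda:        {self.ridge.lam:g}",
            ]
        )


def _concat(pca_features, cnn_features, n_pca=None, n_cnn=None) -> np.ndarray:
    Zp = np.atleast_2d(np.asarray(pca_features, dtype=np.float64))
    Zc = np.atleast_2d(np.asarray(cnn_features, dtype=np.float64))
    if Zp.shape[0] != Zc.shape[0]:
        raise ValidationError(
            f"feature row counts differ: {Zp.shape[0]} vs {Zc.shape[0]}"
        )
    if n_pca is not None and Zp.shape[1] != n_pca:
        raise ValidationError(f"expected {n_pca} PCA features, got {Zp.shape[1]}")
    if n_cnn is not None and Zc.shape[1] != n_cnn:
        raise ValidationError(f"expected {n_cnn} CNN features, got {Zc.shape[1]}")
    return np.hstack([Zp, Zc])


class HybridRidge:
    """Model builder; ``fit`` selects lambda by exact LOO and fits the ridge."""

    def __init__(self, pca_features, cnn_features, y, lambda_grid=None):
        self.X = _concat(pca_features, cnn_features)
        self.n_pca = np.atleast_2d(np.asarray(pca_features)).shape[1]
        self.n_cnn = self.X.shape[1] - self.n_pca
        self.y = np.asarray(y, dtype=np.float64)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValidationError("feature and target row counts differ")
        self.lambda_grid = (
            DEFAULT_LAMBDA_GRID if lambda_grid is None else tuple(lambda_grid)
        )

    def fit(self) -> HybridResults:
        lam = select_lambda_loo(self.X, self.y, self.lambda_grid)
        ridge = fit_ridge(self.X, self.y, lam)
        return HybridResults(ridge=ridge, n_pca=self.n_pca, n_cnn=self.n_cnn)


def fit_hybrid(pca_features, cnn_features, y, lambda_grid=None) -> HybridResults:
    """Concatenate features and fit the lambda-selected ridge."""
    return HybridRidge(pca_features, cnn_features, y, lambda_grid).fit()
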