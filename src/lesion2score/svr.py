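"""Epsilon-insensitive support vector regression with an RBF kernel.

Solves  min 1/2 ||w||^2 + C * sum_i (xi_i + xi_i*)  subject to the epsilon
tube constraints, in the feature space induced by K(x, x') =
exp(-gamma ||x - x'||^2).  The quadratic program is delegated to libSVM via
scikit-learn; this module owns the configuration contract (C = 50,
epsilon = 0.1, gamma = 1/n_features by default) and the primal/dual objective
bookkeeping used to verify solutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.svm import SVR as _SKSVR

from .exceptions import ConfigurationError, ValidationError


@dataclass(frozen=True)
class SVRConfig:
    """Learning parameters of the epsilon-SVR.

    ``gamma=None`` means 1 / n_features, resolved at fit time.
    ``tol`` is the libSVM stopping tolerance; the tight default keeps the
    KKT conditions sharp enough for objective-level verification.
    """

    C: float = 50.0
    epsilon: float = 0.1
    gamma: float | None = None
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ConfigurationError("C must be positive")
        if self.epsilon < 0:
            raise ConfigurationError("epsilon must be non-negative")
        if self.gamma is not None and self.gamma <= 0:
            raise ConfigurationError("gamma must be positive")

    def resolve_gamma(self, n_features: int) -> float:
        return self.gamma if self.gamma is not None else 1.0 / n_features


@dataclass
class SVRResults:
    """Fitted epsilon-SVR: f(x) = sum_i alpha_i K(sv_i, x) + b."""

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    config: SVRConfig
    nobs: int

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if len(self.support_vectors) == 0:  # flat solution: f(x) = b
            return np.full(X.shape[0], self.intercept)
        K = rbf_kernel(X, self.support_vectors, gamma=self.gamma)
        return K @ self.dual_coef + self.intercept

    def primal_objective(self, X, y) -> float:
        """1/2 ||w||^2 (via the kernel trick) + C * total epsilon-slack."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if len(self.support_vectors) == 0:
            w2 = 0.0
        else:
            Ksv = rbf_kernel(self.support_vectors, self.support_vectors, gamma=self.gamma)
            w2 = float(self.dual_coef @ Ksv @ self.dual_coef)
        slack = np.maximum(0.0, np.abs(y - self.predict(X)) - self.config.epsilon)
        return 0.5 * w2 + self.config.C * float(slack.sum())

    def summary(self) -> str:
        return "\n".join(
            [
                "Epsilon-SVR results (RBF kernel)",
                "--------------------------------",
                f"n obs:             {self.nobs}",
                f"support vectors:   {len(self.support_vectors)}",
                f"C / epsilon:       {self.config.C:g} / {self.config.epsilon:g}",
                f"gamma:             {self.gamma:.6g}",
                f"bias b:            {self.intercept:.6g}",
                f"max |dual coef|:   {np.abs(self.dual_coef).max(initial=0.0):.6g}",
            ]
        )

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            support_vectors=self.support_vectors,
            dual_coef=self.dual_coef,
            intercept=self.intercept,
            gamma=self.gamma,
            C=self.config.C,
            epsilon=self.config.epsilon,
            tol=self.config.tol,
            nobs=self.nobs,
        )

    @classmethod
    def load(cls, path) -> "SVRResults":
        with np.load(path) as z:
            return cls(
                support_vectors=z["support_vectors"],
                dual_coef=z["dual_coef"],
                intercept=float(z["intercept"]),
                gamma=float(z["gamma"]),
                config=SVRConfig(
                    C=float(z["C"]), epsilon=float(z["epsilon"]), tol=float(z["tol"])
                ),
                nobs=int(z["nobs"]),
            )


class SupportVectorRegression:
    """Model builder for epsilon-SVR; ``fit`` returns :class:`SVRResults`."""

    def __init__(self, X, y, config: SVRConfig | None = None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != y.shape[0]:
            raise ValidationError("X and y row counts differ")
        if X.shape[0] < 2:
            raise ValidationError("SVR needs at least two training points")
        self.X, self.y = X, y
        self.config = config or SVRConfig()

    def fit(self) -> SVRResults:
        gamma = self.config.resolve_gamma(self.X.shape[1])
        svr = _SKSVR(
            kernel="rbf",
            C=self.config.C,
            epsilon=self.config.epsilon,
            gamma=gamma,
            tol=self.config.tol,
            cache_size=200,
            max_iter=-1,
        )
        svr.fit(self.X, self.y)
        return SVRResults(
            support_vectors=np.asarray(svr.support_vectors_, dtype=np.float64),
            dual_coef=np.asarray(svr.dual_coef_, dtype=np.float64).ravel(),
            intercept=float(np.ravel(svr.intercept_)[0]),
            gamma=gamma,
            config=self.config,
            nobs=self.X.shape[0],
        )


def fit_svr(X, y, config: SVRConfig | None = None) -> SVRResults:
    """Fit an epsilon-SVR with the stated objective (libSVM backend)."""
    return SupportVectorRegression(X, y, config).fit()


def fit_svr_precomputed(K_train: np.ndarray, y, config: SVRConfig) -> _SKSVR:
    """Fit epsilon-SVR on a precomputed RBF kernel matrix.

    Fast path for the LOOCV harness on raw flattened images, where the full
    cohort kernel is derived once from the Gram matrix; predictions on held-out
    rows use ``estimator.predict(K[test, train])``.  Identical solution to
    :func:`fit_svr` on the underlying vectors (same libSVM problem).
    """
    svr = _SKSVR(
        kernel="precomputed",
        C=config.C,
        epsilon=config.epsilon,
        tol=config.tol,
        cache_size=200,
        max_iter=-1,
    )
    svr.fit(np.asarray(K_train, dtype=np.float64), np.asarray(y, dtype=np.float64))
    return svr
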