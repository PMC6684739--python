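"""Ridge regression with leave-one-out lambda selection.

The model minimizes  sum_i (w'x_i - y_i)^2 + lambda * ||w||^2  with an
unpenalized intercept fitted on centred data.  Solutions are computed from a
single SVD of the centred design, which also yields the *exact* leave-one-out
residuals for every candidate lambda at once via the linear-smoother identity
e_(-i) = (y_i - yhat_i) / (1 - h_ii); the grid search over lambda therefore
costs one decomposition, not n refits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, ValidationError

#: Default lambda grid, 1..150 inclusive.
DEFAULT_LAMBDA_GRID = tuple(range(1, 151))

_SVAL_RTOL = 1e-12


def _validate_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValidationError(f"incompatible shapes X{X.shape}, y{y.shape}")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in ridge inputs")
    return X, y


@dataclass
class RidgeResults:
    """Fitted ridge solution.

    ``params`` minimizes the penalized least-squares cost at ``lam``; with
    ``lam = 0`` it is the (minimum-norm) OLS solution.
    """

    params: np.ndarray
    intercept: float
    lam: float
    nobs: int
    fit_intercept: bool = True
    loo_mse: float | None = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.params + self.intercept

    def summary(self) -> str:
        lines = [
            "Ridge regression results",
            "------------------------",
            f"n obs:            {self.nobs}",
            f"n features:       {self.params.size}",
            f"lambda:           {self.lam:g}",
            f"intercept:        {self.intercept:.6g}",
            f"||w||_2:          {np.linalg.norm(self.params):.6g}",
        ]
        if self.loo_mse is not None:
            lines.append(f"LOO MSE:          {self.loo_mse:.6g}")
        return "\n".join(lines)

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            params=self.params,
            intercept=self.intercept,
            lam=self.lam,
            nobs=self.nobs,
            fit_intercept=self.fit_intercept,
        )

    @classmethod
    def load(cls, path) -> "RidgeResults":
        with np.load(path) as z:
            return cls(
                params=z["params"],
                intercept=float(z["intercept"]),
                lam=float(z["lam"]),
                nobs=int(z["nobs"]),
                fit_intercept=bool(z["fit_intercept"]),
            )


class RidgeRegression:
    """Ridge model builder; ``fit`` returns :class:`RidgeResults`.

    Parameters
    ----------
    X, y : array-like
        Training design (n, d) and targets (n,).
    lam : float, optional
        Regularization coefficient.  If None, chosen on ``lambda_grid`` by
        exact leave-one-out MSE (ties broken toward larger lambda).
    lambda_grid : iterable of float
        Candidate lambdas; default 1..150.
    fit_intercept : bool
        Fit an unpenalized intercept on centred data (default True).
    """

    def __init__(self, X, y, lam: float | None = None, lambda_grid=None, fit_intercept=True):
        self.X, self.y = _validate_xy(X, y)
        if lam is not None and lam < 0:
            raise ConfigurationError("lambda must be non-negative")
        self.lam = lam
        self.lambda_grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else tuple(lambda_grid)
        self.fit_intercept = fit_intercept

    def fit(self) -> RidgeResults:
        lam = self.lam
        loo = None
        if lam is None:
            lam, errs = select_lambda_loo(
                self.X, self.y, self.lambda_grid, self.fit_intercept, return_errors=True
            )
            loo = float(errs[self.lambda_grid.index(lam)])
        res = fit_ridge(self.X, self.y, lam, self.fit_intercept)
        res.loo_mse = loo
        return res


def fit_ridge(X, y, lam: float, fit_intercept: bool = True) -> RidgeResults:
    """Solve the ridge problem exactly via SVD of the (centred) design."""
    X, y = _validate_xy(X, y)
    if lam < 0:
        raise ConfigurationError("lambda must be non-negative")
    if fit_intercept:
        x_mean, y_mean = X.mean(axis=0), y.mean()
    else:
        x_mean, y_mean = np.zeros(X.shape[1]), 0.0
    Xc, yc = X - x_mean, y - y_mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if lam == 0:
        d = np.where(s > _SVAL_RTOL * max(s.max(initial=0.0), 1e-300), 1.0 / np.where(s == 0, 1, s), 0.0)
    else:
        d = s / (s**2 + lam)
    w = Vt.T @ (d * (U.T @ yc))
    intercept = float(y_mean - x_mean @ w)
    return RidgeResults(
        params=w,
        intercept=intercept,
        lam=float(lam),
        nobs=X.shape[0],
        fit_intercept=fit_intercept,
    )


def loo_squared_errors(X, y, lambdas, fit_intercept: bool = True) -> np.ndarray:
    """Mean squared exact-LOO prediction error for each candidate lambda.

    Uses one SVD: with hat diagonal h_ii(lam) = 1/n + sum_j U_ij^2 d_j(lam)
    (the 1/n term from the unpenalized intercept), the left-out residual is
    (y_i - yhat_i) / (1 - h_ii), exactly.
    """
    X, y = _validate_xy(X, y)
    lambdas = np.asarray(list(lambdas), dtype=np.float64)
    if lambdas.size == 0:
        raise ConfigurationError("empty lambda grid")
    if (lambdas < 0).any():
        raise ConfigurationError("lambdas must be non-negative")
    n = X.shape[0]
    if n < 3:
        raise ValidationError("leave-one-out selection needs n >= 3")
    if fit_intercept:
        x_mean, y_mean = X.mean(axis=0), y.mean()
    else:
        x_mean, y_mean = np.zeros(X.shape[1]), 0.0
    Xc, yc = X - x_mean, y - y_mean
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    Uy = U.T @ yc
    U2 = U**2
    base_h = 1.0 / n if fit_intercept else 0.0
    out = np.empty(lambdas.size)
    for j, lam in enumerate(lambdas):
        d = s**2 / (s**2 + lam) if lam > 0 else (s > _SVAL_RTOL * max(s.max(initial=0.0), 1e-300)).astype(float)
        resid = yc - U @ (d * Uy)
        h = base_h + U2 @ d
        denom = 1.0 - h
        denom = np.where(np.abs(denom) < 1e-12, np.sign(denom + 1e-300) * 1e-12, denom)
        out[j] = float(np.mean((resid / denom) ** 2))
    return out


def select_lambda_loo(X, y, grid=None, fit_intercept: bool = True, return_errors: bool = False):
    """Grid value minimizing exact-LOO MSE; ties broken toward larger lambda."""
    grid = DEFAULT_LAMBDA_GRID if grid is None else tuple(grid)
    if len(grid) == 0:
        raise ConfigurationError("empty lambda grid")
    errs = loo_squared_errors(X, y, grid, fit_intercept)
    best = errs.min()
    winners = [lam for lam, e in zip(grid, errs) if e <= best * (1 + 1e-12)]
    chosen = max(winners)
    if return_errors:
        return chosen, errs
    return chosen
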