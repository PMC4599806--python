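"""Weighted least squares with a survey-weight (pweight) sandwich covariance.

Point estimates solve the weighted normal equations; the variance is the
heteroskedasticity-consistent sandwich built from weight-scaled scores
``w_i * e_i * x_i`` with an HC1-style small-sample factor ``n / (n - k)``.
With unit weights this reduces to OLS with robust (HC1) standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats


class RankDeficientDesignError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear column(s): "
            + ", ".join(self.columns)
        )


@dataclass
class WlsFit:
    """A fitted weighted linear model.

    Attributes
    ----------
    params : coefficient vector, ordered as the design columns.
    cov_robust : pweight sandwich covariance (HC1 small-sample factor).
    cov_classical : classical (model-based) WLS covariance.
    names : design column names.
    """

    params: np.ndarray
    cov_robust: np.ndarray
    cov_classical: np.ndarray
    names: list[str]
    n: int
    k: int
    resid: np.ndarray = field(repr=False)

    def se(self, robust: bool = True) -> np.ndarray:
        cov = self.cov_robust if robust else self.cov_classical
        return np.sqrt(np.diag(cov))

    def z(self, robust: bool = True) -> np.ndarray:
        return self.params / self.se(robust)

    def p(self, robust: bool = True) -> np.ndarray:
        """Two-sided Wald p-values from the standard-normal reference."""
        return 2.0 * stats.norm.sf(np.abs(self.z(robust)))

    def contrast(self, c: np.ndarray, robust: bool = True) -> tuple[float, float]:
        """1-df Wald test of ``c @ params = 0``; returns (z, two-sided p)."""
        c = np.asarray(c, dtype=float)
        cov = self.cov_robust if robust else self.cov_classical
        num = float(c @ self.params)
        den = float(np.sqrt(c @ cov @ c))
        z = num / den
        return z, 2.0 * stats.norm.sf(abs(z))


def _find_collinear(X: np.ndarray, names: list[str]) -> list[str]:
    # QR with column pivoting: columns whose R diagonal collapses are the
    # ones that add no rank.
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.max() > 0 else 0.0
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if not bad and diag.size < X.shape[1]:
        bad = [names[j] for j in piv[diag.size:]]
    return bad


def wls_fit(
    y: np.ndarray,
    X: np.ndarray,
    weights: np.ndarray | None = None,
    names: Sequence[str] | None = None,
) -> WlsFit:
    """Fit ``y ~ X`` by weighted least squares with sandwich covariance.

    Parameters
    ----------
    y : response vector, no missing values.
    X : (n, k) design matrix, intercept column included by the caller.
    weights : sampling weights (inverse inclusion probabilities); ``None``
        means unit weights.
    names : optional design column names used in error messages and results.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    n, k = X.shape
    if y.shape != (n,):
        raise ValueError("y and X have incompatible shapes")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values in assembled design; drop them first")
    if n <= k:
        raise ValueError(f"need more observations ({n}) than parameters ({k})")
    names = list(names) if names is not None else [f"x{j}" for j in range(k)]
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights must match the number of observations")
        if (w <= 0).any() or np.isnan(w).any():
            raise ValueError("weights must be strictly positive")

    Xw = X * w[:, None]
    A = X.T @ Xw                      # X' W X
    if np.linalg.matrix_rank(A) < k:
        raise RankDeficientDesignError(_find_collinear(np.sqrt(w)[:, None] * X, names))
    A_inv = np.linalg.inv(A)
    beta = A_inv @ (Xw.T @ y)
    resid = y - X @ beta

    # pweight sandwich: meat from weight-scaled scores, HC1 factor n/(n-k).
    score = Xw * resid[:, None]
    meat = score.T @ score
    cov_robust = A_inv @ meat @ A_inv * (n / (n - k))

    # classical WLS covariance: sigma^2 (X'WX)^-1 with weighted RSS.
    sigma2 = float(resid @ (w * resid)) / (n - k)
    cov_classical = A_inv * sigma2

    return WlsFit(
        params=beta,
        cov_robust=cov_robust,
        cov_classical=cov_classical,
        names=names,
        n=n,
        k=k,
        resid=resid,
    )


def drop_constant_columns(
    X: np.ndarray, names: list[str], keep: int = 1
) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop covariate columns with zero variance (collinear with intercept).

    The first ``keep`` columns (the intercept) are never dropped. Returns
    (reduced X, kept names, dropped names).
    """
    dropped, cols = [], []
    for j in range(X.shape[1]):
        if j >= keep and np.ptp(X[:, j]) == 0.0:
            dropped.append(names[j])
        else:
            cols.append(j)
    return X[:, cols], [names[j] for j in cols], dropped
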