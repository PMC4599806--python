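"""Fixed-effect meta-analysis of per-study association summaries.

Two poolers are provided, matching common practice in family-study
consortia: a signed-z (Stouffer) combination with sqrt(sample-size)
weights, and inverse-variance weighting of the betas. Studies reporting
only (beta, p) get a standard error back-calculated as SE = |beta| / |z|
with z the normal quantile of the two-sided p — the usual conversion when
the underlying software reports no SE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


def z_from_p(p: float, sign: float = 1.0) -> float:
    """Signed z-statistic from a two-sided p-value.

    z = sign * Phi^-1(1 - p/2); p = 1 maps to z = 0.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    return float(np.sign(sign) if sign != 0 else 1.0) * float(stats.norm.isf(p / 2.0))


def p_from_z(z: float) -> float:
    """Two-sided normal tail probability of |z|."""
    return float(2.0 * stats.norm.sf(abs(z)))


def se_from_beta_p(beta: float, p: float) -> float:
    """Back-calculate a standard error from (beta, two-sided p): SE = |beta|/|z|."""
    if beta == 0:
        raise ValueError("beta = 0: standard error undefined")
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1) for SE back-calculation")
    return abs(beta) / abs(z_from_p(p, sign=1.0))


@dataclass(frozen=True)
class StudySummary:
    """One study's summary for one trait and allele origin.

    At least one of ``se`` and ``p_value`` must be present; the z-statistic
    is beta/se when the SE was reported directly, otherwise it is recovered
    from the p-value and carries beta's sign.
    """

    study: str
    beta: float
    n: int
    se: float | None = None
    p_value: float | None = None

    def __post_init__(self):
        if self.se is None and self.p_value is None:
            raise ValueError(f"{self.study}: need se or p_value")
        if self.se is not None and self.se <= 0:
            raise ValueError(f"{self.study}: se must be positive")
        if self.n is not None and self.n <= 0:
            raise ValueError(f"{self.study}: n must be positive")

    @property
    def z(self) -> float:
        if self.se is not None:
            return self.beta / self.se
        return z_from_p(self.p_value, sign=np.sign(self.beta) or 1.0)

    def se_or_derived(self) -> float:
        return self.se if self.se is not None else se_from_beta_p(self.beta, self.p_value)


@dataclass
class MetaResult:
    """A combined estimate; ``beta``/``se`` are None for the z-based method."""

    method: str
    z: float
    p_value: float
    n: int
    beta: float | None = None
    se: float | None = None
    q: float | None = None          # Cochran's Q heterogeneity diagnostic
    q_p: float | None = None
    k: int = 0


def stouffer_meta(
    summaries: Sequence[StudySummary], weighted: bool = True
) -> MetaResult:
    """Signed-z fixed-effect combination (Stouffer).

    With ``weighted=True`` (default) the per-study z's get sqrt(n) weights:
    z* = sum(sqrt(n_i) z_i) / sqrt(sum n_i). Unweighted uses 1/sqrt(k).
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no studies to combine")
    for s in summaries:
        if s.n is None:
            raise ValueError(f"{s.study}: sample size required for z-based meta")
    zs = np.array([s.z for s in summaries])
    if weighted:
        ns = np.array([s.n for s in summaries], dtype=float)
        z = float((np.sqrt(ns) * zs).sum() / np.sqrt(ns.sum()))
    else:
        z = float(zs.sum() / np.sqrt(len(zs)))
    return MetaResult(
        method="stouffer", z=z, p_value=p_from_z(z),
        n=int(sum(s.n for s in summaries)), k=len(summaries),
    )


def inverse_variance_meta(summaries: Sequence[StudySummary]) -> MetaResult:
    """Inverse-variance-weighted fixed-effect pooling of betas.

    beta* = sum(w_i b_i)/sum(w_i) with w_i = 1/se_i^2 and
    se* = (sum w_i)^(-1/2). Cochran's Q is reported as a heterogeneity
    diagnostic (k-1 df).
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no studies to combine")
    betas = np.array([s.beta for s in summaries])
    ses = np.array([s.se_or_derived() for s in summaries])
    if (ses <= 0).any():
        raise ValueError("all standard errors must be positive")
    w = 1.0 / ses**2
    beta = float((w * betas).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = beta / se
    k = len(summaries)
    q = float((w * (betas - beta) ** 2).sum())
    q_p = float(stats.chi2.sf(q, df=k - 1)) if k > 1 else None
    return MetaResult(
        method="inverse_variance", beta=beta, se=se, z=z, p_value=p_from_z(z),
        n=int(sum(s.n for s in summaries if s.n is not None)),
        q=q, q_p=q_p, k=k,
    )


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance cut: alpha / number of tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests
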