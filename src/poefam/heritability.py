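"""Parent-offspring correlation heritability and the share a variant explains.

Under a simple polygenic model the narrow-sense heritability is twice the
mother-offspring trait correlation, h2 = 2 r. The contribution of one
variant's parent-of-origin effect is measured as the relative drop in h2
after residualizing the offspring trait on the variant's parental-origin
dosages (or on the additive genotype, for comparison):

    fraction_explained = (h2_base - h2_adjusted) / h2_base
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._wls import wls_fit


@dataclass
class HeritabilityEstimate:
    trait: str
    h2_base: float
    h2_adjusted: float
    model: str  # "poe_adjusted" | "additive_adjusted" | "none"
    fraction_explained: float
    n: int
    clamped: bool = False


def _weighted_corr(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    mx, my = (w * x).sum(), (w * y).sum()
    cov = (w * (x - mx) * (y - my)).sum()
    vx = (w * (x - mx) ** 2).sum()
    vy = (w * (y - my) ** 2).sum()
    return float(cov / np.sqrt(vx * vy))


def _residualize(y: np.ndarray, covars: np.ndarray | None, w: np.ndarray) -> np.ndarray:
    if covars is None:
        return y
    covars = np.asarray(covars, dtype=float)
    if covars.ndim == 1:
        covars = covars[:, None]
    X = np.column_stack([np.ones(len(y)), covars])
    fit = wls_fit(y, X, w)
    return fit.resid


def mo_heritability(
    mother_trait,
    offspring_trait,
    offspring_covars=None,
    mother_covars=None,
    weights=None,
) -> tuple[float, bool]:
    """h2 = 2 * weighted Pearson correlation of (residualized) traits.

    ``offspring_covars``/``mother_covars`` are regressed out of the
    respective trait first (weighted least squares with intercept).
    Returns (h2, clamped) with h2 clamped into [0, 1].
    """
    m = np.asarray(mother_trait, dtype=float)
    o = np.asarray(offspring_trait, dtype=float)
    if m.shape != o.shape:
        raise ValueError("mother and offspring trait vectors must align")
    if len(m) < 10:
        raise ValueError("need at least 10 mother-offspring pairs")
    w = np.ones(len(m)) if weights is None else np.asarray(weights, dtype=float)
    m_res = _residualize(m, mother_covars, w)
    o_res = _residualize(o, offspring_covars, w)
    r = _weighted_corr(m_res, o_res, w)
    h2 = 2.0 * r
    clamped = not (0.0 <= h2 <= 1.0)
    return float(np.clip(h2, 0.0, 1.0)), clamped


def poe_heritability_explained(
    mother_trait,
    offspring_trait,
    g_md,
    g_pd,
    weights=None,
    trait: str = "",
    model: str = "poe_adjusted",
) -> HeritabilityEstimate:
    """Fraction of parent-offspring heritability attributed to one variant.

    ``model="poe_adjusted"`` residualizes the offspring trait on the two
    parental-origin dosages; ``"additive_adjusted"`` residualizes on their
    sum (the offspring genotype). If the variant is independent of the
    trait the residualization changes nothing and the fraction is ~0.
    """
    g_md = np.asarray(g_md, dtype=float)
    g_pd = np.asarray(g_pd, dtype=float)
    if model == "poe_adjusted":
        covars = np.column_stack([g_md, g_pd])
    elif model == "additive_adjusted":
        covars = (g_md + g_pd)[:, None]
    else:
        raise ValueError(f"unknown model {model!r}")
    h2_base, c1 = mo_heritability(mother_trait, offspring_trait, weights=weights)
    h2_adj, c2 = mo_heritability(
        mother_trait, offspring_trait, offspring_covars=covars, weights=weights
    )
    if h2_base == 0.0:
        frac = 0.0
    else:
        frac = (h2_base - h2_adj) / h2_base
    return HeritabilityEstimate(
        trait=trait, h2_base=h2_base, h2_adjusted=h2_adj, model=model,
        fraction_explained=float(frac), n=len(g_md), clamped=c1 or c2,
    )
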