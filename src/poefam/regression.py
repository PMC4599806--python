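"""Additive and parental-origin weighted regression models.

Model 1 (additive):            E[Y] = b0 + b_G * G_O           + g'Z
Model 2 (parental origin):     E[Y] = b0 + b_MD*G_MD + b_PD*G_PD + g'Z

where G_O is the offspring minor-allele count and G_MD/G_PD the maternally-
and paternally-derived dosages (G_MD + G_PD = G_O). Fits are weighted least
squares with survey-weight sandwich standard errors; Wald p-values use the
standard-normal reference. Three null hypotheses are tested on model 2:
b_MD = 0, b_PD = 0 and b_MD = b_PD (1-df contrast, the equality "F-test").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._wls import RankDeficientDesignError, WlsFit, drop_constant_columns, wls_fit

#: The nine grandparental-origin strata; the reference stratum is dropped
#: from the design to avoid complete multicollinearity.
STRATA = (
    "israel",
    "morocco",
    "north_africa",
    "iran",
    "iraq",
    "kurdistan",
    "yemen",
    "asia_balkans",
    "ashkenazi",
)
REFERENCE_STRATUM = "ashkenazi"


def build_ancestry_covariates(
    grandparent_origins: Sequence[str],
    strata: Sequence[str] = STRATA,
    reference: str = REFERENCE_STRATUM,
) -> pd.Series:
    """Per-stratum grandparental proportions, reference stratum dropped.

    ``grandparent_origins`` gives the stratum of each of the 4 grandparents;
    the returned proportions are counts/4 for every non-reference stratum,
    so each entry lies in {0, 0.25, 0.5, 0.75, 1} and the full set of nine
    proportions (including the implicit reference) sums to 1.
    """
    if len(grandparent_origins) != 4:
        raise ValueError("expected 4 grandparental origin codes")
    known = set(strata)
    out = {s: 0.0 for s in strata if s != reference}
    for code in grandparent_origins:
        code = str(code).lower()
        if code not in known:
            raise ValueError(f"unknown ancestry stratum {code!r}")
        if code != reference:
            out[code] += 0.25
    return pd.Series(out)


def ancestry_design(
    origins: pd.DataFrame,
    strata: Sequence[str] = STRATA,
    reference: str = REFERENCE_STRATUM,
) -> pd.DataFrame:
    """Vectorized ancestry proportions for a table of 4 origin columns."""
    cols = [c for c in origins.columns if c.startswith("gp_origin")]
    if len(cols) != 4:
        raise ValueError("expected 4 gp_origin_* columns")
    out = pd.DataFrame(0.0, index=origins.index,
                       columns=[s for s in strata if s != reference])
    known = set(strata)
    for c in cols:
        codes = origins[c].astype(str).str.lower()
        bad = set(codes) - known
        if bad:
            raise ValueError(f"unknown ancestry stratum {sorted(bad)[0]!r}")
        for s in out.columns:
            out[s] += 0.25 * (codes == s).to_numpy()
    return out


@dataclass
class AdditiveFitResult:
    """Model-1 fit: the additive per-minor-allele effect."""

    beta_g: float
    se: float
    p_value: float
    n: int
    intercept: float
    gamma: pd.Series
    fit: WlsFit = field(repr=False)


@dataclass
class PoeFitResult:
    """Model-2 fit: maternally- and paternally-derived effects.

    ``f_p`` is the two-sided p-value of the 1-df equality contrast
    b_MD = b_PD on the robust covariance (``f_p_classical`` uses the
    model-based covariance).
    """

    beta_md: float
    se_md: float
    p_md: float
    beta_pd: float
    se_pd: float
    p_pd: float
    f_p: float
    f_p_classical: float
    n: int
    intercept: float
    gamma: pd.Series
    fit: WlsFit = field(repr=False)


def _assemble(
    columns: list[tuple[str, np.ndarray]],
    z: pd.DataFrame | np.ndarray | None,
) -> tuple[np.ndarray, list[str], list[str]]:
    n = len(columns[0][1])
    names = ["intercept"] + [name for name, _ in columns]
    mats = [np.ones(n)] + [np.asarray(col, dtype=float) for _, col in columns]
    if z is not None:
        if isinstance(z, pd.DataFrame):
            znames = [str(c) for c in z.columns]
            zmat = z.to_numpy(dtype=float)
        else:
            zmat = np.asarray(z, dtype=float)
            if zmat.ndim == 1:
                zmat = zmat[:, None]
            znames = [f"z{j}" for j in range(zmat.shape[1])]
        names += znames
        mats += [zmat[:, j] for j in range(zmat.shape[1])]
    X = np.column_stack(mats)
    X, names, dropped = drop_constant_columns(X, names)
    if dropped:
        warnings.warn(
            f"dropped constant covariate column(s): {', '.join(dropped)}",
            stacklevel=3,
        )
    return X, names, dropped


class AdditiveRegression(RegressorMixin, BaseEstimator):
    """Additive genotype model fitted by weighted least squares.

    The first column of ``X`` is the offspring minor-allele count; any
    further columns are adjustment covariates. Sampling weights enter as
    ``sample_weight`` with pweight semantics (WLS point estimates, sandwich
    variance).

    Attributes (after fit)
    ----------------------
    beta_g_, se_, p_value_ : the additive effect, its robust SE and Wald p.
    coef_, intercept_ : full coefficient vector (sklearn convention).
    """

    def __init__(self, robust: bool = True):
        self.robust = robust

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        names = ["g_o"] + [f"z{j}" for j in range(X.shape[1] - 1)]
        design, names, _ = _assemble(
            [("g_o", X[:, 0])], X[:, 1:] if X.shape[1] > 1 else None
        )
        fit = wls_fit(y, design, sample_weight, names=names)
        self._store(fit)
        return self

    def _store(self, fit: WlsFit):
        se = fit.se(self.robust)
        p = fit.p(self.robust)
        j = fit.names.index("g_o")
        self.fit_ = fit
        self.beta_g_ = float(fit.params[j])
        self.se_ = float(se[j])
        self.p_value_ = float(p[j])
        self.intercept_ = float(fit.params[0])
        self.coef_ = fit.params[1:].copy()
        self.feature_names_ = fit.names[1:]
        self.n_obs_ = fit.n
        self.n_features_in_ = len(fit.names) - 1

    def predict(self, X):
        check_is_fitted(self, "fit_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X[:, : len(self.coef_)] @ self.coef_

    def result(self) -> AdditiveFitResult:
        check_is_fitted(self, "fit_")
        gamma = pd.Series(self.coef_[1:], index=self.feature_names_[1:])
        return AdditiveFitResult(
            beta_g=self.beta_g_, se=self.se_, p_value=self.p_value_,
            n=self.n_obs_, intercept=self.intercept_, gamma=gamma, fit=self.fit_,
        )


class ParentOfOriginRegression(RegressorMixin, BaseEstimator):
    """Parental-origin model fitted by weighted least squares.

    The first two columns of ``X`` are the maternally- and paternally-
    derived dosages (g_md, g_pd); further columns are covariates. With
    ``constrained=True`` the two dosage coefficients are forced equal by
    fitting on their sum — because g_md + g_pd equals the offspring
    genotype, this reproduces the additive model exactly.

    Attributes (after fit)
    ----------------------
    beta_md_, se_md_, p_md_ : maternal effect, robust SE, Wald p.
    beta_pd_, se_pd_, p_pd_ : paternal counterpart.
    f_p_ : p-value of the 1-df equality contrast b_MD = b_PD.
    """

    def __init__(self, robust: bool = True, constrained: bool = False):
        self.robust = robust
        self.constrained = constrained

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X needs at least the g_md and g_pd columns")
        y = np.asarray(y, dtype=float)
        z = X[:, 2:] if X.shape[1] > 2 else None
        if self.constrained:
            design, names, _ = _assemble([("g_o", X[:, 0] + X[:, 1])], z)
            fit = wls_fit(y, design, sample_weight, names=names)
            j = names.index("g_o")
            se = fit.se(self.robust)
            p = fit.p(self.robust)
            self.fit_ = fit
            self.beta_md_ = self.beta_pd_ = float(fit.params[j])
            self.se_md_ = self.se_pd_ = float(se[j])
            self.p_md_ = self.p_pd_ = float(p[j])
            self.f_p_ = self.f_p_classical_ = 1.0  # equality imposed
            self.intercept_ = float(fit.params[0])
            self.coef_ = fit.params[1:].copy()
            self.feature_names_ = fit.names[1:]
            self.n_obs_ = fit.n
            self.n_features_in_ = X.shape[1]
            return self
        try:
            design, names, _ = _assemble(
                [("g_md", X[:, 0]), ("g_pd", X[:, 1])], z
            )
            fit = wls_fit(y, design, sample_weight, names=names)
        except RankDeficientDesignError as exc:
            if {"g_md", "g_pd"} & set(exc.columns):
                raise RankDeficientDesignError(exc.columns) from None
            raise
        jm, jp = names.index("g_md"), names.index("g_pd")
        se = fit.se(self.robust)
        p = fit.p(self.robust)
        contrast = np.zeros(len(names))
        contrast[jm], contrast[jp] = 1.0, -1.0
        _, f_p = fit.contrast(contrast, robust=self.robust)
        _, f_p_classical = fit.contrast(contrast, robust=False)
        self.fit_ = fit
        self.beta_md_ = float(fit.params[jm])
        self.se_md_ = float(se[jm])
        self.p_md_ = float(p[jm])
        self.beta_pd_ = float(fit.params[jp])
        self.se_pd_ = float(se[jp])
        self.p_pd_ = float(p[jp])
        self.f_p_ = float(f_p)
        self.f_p_classical_ = float(f_p_classical)
        self.intercept_ = float(fit.params[0])
        self.coef_ = fit.params[1:].copy()
        self.feature_names_ = fit.names[1:]
        self.n_obs_ = fit.n
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "fit_")
        X = np.asarray(X, dtype=float)
        if self.constrained:
            cols = np.column_stack([X[:, 0] + X[:, 1], X[:, 2:]]) if X.shape[1] > 2 \
                else (X[:, 0] + X[:, 1])[:, None]
            return self.intercept_ + cols[:, : len(self.coef_)] @ self.coef_
        return self.intercept_ + X[:, : len(self.coef_)] @ self.coef_

    def result(self) -> PoeFitResult:
        check_is_fitted(self, "fit_")
        skip = 1 if self.constrained else 2
        gamma = pd.Series(self.coef_[skip:], index=self.feature_names_[skip:])
        return PoeFitResult(
            beta_md=self.beta_md_, se_md=self.se_md_, p_md=self.p_md_,
            beta_pd=self.beta_pd_, se_pd=self.se_pd_, p_pd=self.p_pd_,
            f_p=self.f_p_, f_p_classical=self.f_p_classical_,
            n=self.n_obs_, intercept=self.intercept_, gamma=gamma, fit=self.fit_,
        )


def _stack(g1, g2=None, z=None) -> np.ndarray:
    cols = [np.asarray(g1, dtype=float)]
    if g2 is not None:
        cols.append(np.asarray(g2, dtype=float))
    if z is not None:
        zmat = z.to_numpy(dtype=float) if isinstance(z, pd.DataFrame) else np.asarray(z, dtype=float)
        if zmat.ndim == 1:
            zmat = zmat[:, None]
        cols.extend(zmat[:, j] for j in range(zmat.shape[1]))
    return np.column_stack(cols)


def fit_additive(y, g_o, z=None, weights=None, robust: bool = True) -> AdditiveFitResult:
    """Fit the additive model; thin wrapper over :class:`AdditiveRegression`."""
    est = AdditiveRegression(robust=robust).fit(_stack(g_o, z=z), y, sample_weight=weights)
    return est.result()


def fit_poe(
    y, g_md, g_pd, z=None, weights=None, robust: bool = True,
    constrained: bool = False,
) -> PoeFitResult:
    """Fit the parental-origin model; wrapper over :class:`ParentOfOriginRegression`."""
    est = ParentOfOriginRegression(robust=robust, constrained=constrained)
    est.fit(_stack(g_md, g_pd, z=z), y, sample_weight=weights)
    return est.result()


def adjust_for_bmi(
    y, g_md, g_pd, z, bmi, weights=None, trait: str = "", robust: bool = True
) -> tuple[PoeFitResult, PoeFitResult]:
    """Refit model 2 with BMI appended to the covariates.

    Returns (unadjusted, adjusted) results. Refuses to adjust the BMI trait
    for itself.
    """
    if trait.lower() == "bmi":
        raise ValueError("cannot adjust BMI for BMI")
    unadj = fit_poe(y, g_md, g_pd, z=z, weights=weights, robust=robust)
    bmi = np.asarray(bmi, dtype=float)
    if z is None:
        z2 = pd.DataFrame({"bmi": bmi})
    elif isinstance(z, pd.DataFrame):
        z2 = z.copy()
        z2["bmi"] = bmi
    else:
        z2 = np.column_stack([np.asarray(z, dtype=float), bmi])
    adj = fit_poe(y, g_md, g_pd, z=z2, weights=weights, robust=robust)
    return unadj, adj


def discovery_screen(
    results: pd.DataFrame,
    gene_map: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Select SNPs to move forward from per-SNP-per-trait model-2 tests.

    A SNP is forwarded if, for any examined trait, its maternal or paternal
    Wald p beats the within-gene Bonferroni cut (alpha / number of SNPs in
    the gene) while the equality test is nominally significant
    (f_p < alpha).

    Parameters
    ----------
    results : DataFrame with columns snp_id, trait, p_md, p_pd, f_p.
    gene_map : mapping of snp_id -> gene symbol; must cover all SNPs.

    Returns
    -------
    Per-SNP frame with gene, k_gene, forwarded flag and the triggering
    traits (';'-joined).
    """
    required = {"snp_id", "trait", "p_md", "p_pd", "f_p"}
    if not required <= set(results.columns):
        raise ValueError(f"results must have columns {sorted(required)}")
    missing = set(results["snp_id"]) - set(gene_map)
    if missing:
        raise ValueError(f"gene_map does not cover SNP(s): {sorted(missing)}")
    k_gene = pd.Series(gene_map).value_counts()

    rows = []
    for snp, grp in results.groupby("snp_id", sort=False):
        gene = gene_map[snp]
        k = int(k_gene[gene])
        cut = alpha / k
        hits = grp[
            ((grp["p_md"] < cut) | (grp["p_pd"] < cut)) & (grp["f_p"] < alpha)
        ]
        rows.append(dict(
            snp_id=snp, gene=gene, k_gene=k,
            forwarded=bool(len(hits)),
            traits=";".join(hits["trait"].astype(str)),
        ))
    return pd.DataFrame(rows).set_index("snp_id")
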