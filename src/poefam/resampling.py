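"""Permutation null for the maternal parent-of-origin Wald statistic.

The null hypothesis of no parent-of-origin effect makes the parental
origin of an offspring's alleles uninformative: given the offspring
genotype, the maternal/paternal labelling of its two allele dosages is
exchangeable. Each permutation replicate therefore re-randomizes the
labels, refits the parental-origin model and records the maternal Wald z;
the empirical two-sided p uses the add-one convention (r+1)/(B+1). Every
offspring genotype and the phenotype vector are preserved exactly — the
dosage pair always sums to the offspring count, so any additive genetic
signal survives — while the maternal/paternal split, the quantity under
test, is destroyed.

Three label-randomization schemes are available:

``swap`` (default)
    Each pair independently swaps its (g_md, g_pd) dosage pair with
    probability 1/2. Dosage magnitudes are untouched (ambiguous double
    heterozygotes keep their (1-MAF, MAF) split, merely mirrored), so the
    permuted statistic is built from columns with exactly the observed
    structure; because the phenotype is independent of the labelling under
    the null, this sign-flip test is essentially exact.
``redraw``
    Hard origin labels are redrawn Bernoulli(1/2) for every offspring
    carrying exactly one minor allele; homozygotes stay (0,0)/(1,1).
``redraw_mother``
    As ``redraw`` but respecting the mother's genotype: pairs where the
    mother forces the origin keep the forced label and ambiguous pairs
    redraw Bernoulli(1-MAF), the null transmission distribution. Because
    forced labels retain most of a true maternal signal, this variant is
    extremely conservative under the alternative and is provided for
    sensitivity analysis only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._wls import wls_fit
from .dosage import dosage_columns

SCHEMES = ("swap", "redraw", "redraw_mother")


@dataclass
class PermutationResult:
    """Empirical two-sided p for the maternal effect, add-one convention."""

    observed_z: float
    p_value: float
    n_permutations: int
    n_exceed: int
    seed: int
    scheme: str = "swap"


def _design(g_md, g_pd, z):
    cols = [np.ones(len(g_md)), g_md, g_pd]
    if z is not None:
        zmat = np.asarray(z, dtype=float)
        if zmat.ndim == 1:
            zmat = zmat[:, None]
        cols.extend(zmat[:, j] for j in range(zmat.shape[1]))
    return np.column_stack(cols)


def _maternal_z(y, X, w):
    fit = wls_fit(y, X, w)
    return float(fit.params[1] / np.sqrt(fit.cov_robust[1, 1]))


def permute_poe(
    mother: np.ndarray,
    offspring: np.ndarray,
    y: np.ndarray,
    maf: float,
    z=None,
    weights=None,
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "swap",
) -> PermutationResult:
    """Permutation p-value for the maternal Wald statistic of one SNP.

    Parameters
    ----------
    mother, offspring : minor-allele counts per pair; pairs that are
        uninformative or Mendelian-inconsistent are dropped internally.
    y : phenotype vector aligned with the pairs.
    maf : minor allele frequency, used for the observed expected-dosage
        fit (and the ``redraw_mother`` null transmission probabilities).
    z : optional covariate matrix; weights : optional sampling weights.
    n_perm : number of replicates (>= 100, warned otherwise).
    seed : permutation stream seed; fixing it fixes the p-value.
    scheme : label-randomization scheme, see the module docstring.
    """
    mother = np.asarray(mother, dtype=float)
    offspring = np.asarray(offspring, dtype=float)
    y = np.asarray(y, dtype=float)
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value",
                      stacklevel=2)

    g_md, g_pd, cat = dosage_columns(mother, offspring, maf)
    keep = ~np.isnan(g_md)
    if keep.sum() == 0:
        raise ValueError("no informative pairs")
    g_md, g_pd = g_md[keep], g_pd[keep]
    mother_k, offspring_k, y_k = mother[keep], offspring[keep], y[keep]
    zk = None if z is None else np.asarray(z, dtype=float)[keep]
    wk = None if weights is None else np.asarray(weights, dtype=float)[keep]

    X = _design(g_md, g_pd, zk)
    observed = _maternal_z(y_k, X, wk)

    n = len(y_k)
    het = offspring_k == 1
    forced_maternal = het & (mother_k == 2)
    forced_paternal = het & (mother_k == 0)
    ambiguous = het & (mother_k == 1)
    base_md = np.where(offspring_k == 2, 1.0, 0.0)  # homozygotes fixed

    rng = np.random.default_rng(seed)
    exceed = 0
    Xp = X.copy()
    for _ in range(n_perm):
        if scheme == "swap":
            flip = rng.random(n) < 0.5
            Xp[:, 1] = np.where(flip, g_pd, g_md)
            Xp[:, 2] = np.where(flip, g_md, g_pd)
        else:
            md = base_md.copy()
            if scheme == "redraw":
                md[het] = (rng.random(int(het.sum())) < 0.5).astype(float)
            else:  # redraw_mother
                md[forced_maternal] = 1.0
                md[forced_paternal] = 0.0
                md[ambiguous] = (
                    rng.random(int(ambiguous.sum())) < (1.0 - maf)
                ).astype(float)
            Xp[:, 1] = md
            Xp[:, 2] = offspring_k - md
        z_perm = _maternal_z(y_k, Xp, wk)
        if abs(z_perm) >= abs(observed):
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return PermutationResult(
        observed_z=observed, p_value=p, n_permutations=n_perm,
        n_exceed=exceed, seed=seed, scheme=scheme,
    )
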