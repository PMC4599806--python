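"""Maternally/paternally-derived minor-allele dosage from mother-offspring pairs.

Without paternal genotypes, the parental origin of an offspring's minor
allele is deducible from the mother's genotype except when both mother and
offspring are heterozygous. For those ambiguous pairs, under random mating
and transmission equilibrium the minor allele came from the mother with
probability 1 - MAF, so the pair is assigned the expected dosage
(g_md, g_pd) = (1 - MAF, MAF). In every consistent pair the two dosages sum
exactly to the offspring's minor-allele count.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .families import GenotypeTable, estimate_maf


class Category(str, enum.Enum):
    UNAMBIGUOUS = "unambiguous"
    AMBIGUOUS = "ambiguous"
    UNINFORMATIVE = "uninformative"
    INCONSISTENT = "inconsistent"


@dataclass(frozen=True)
class PoeDosage:
    """Parental-origin dosage pair for one mother-offspring pair at one SNP."""

    g_md: float
    g_pd: float
    category: Category


def poe_dosage(mother_count, offspring_count, maf: float) -> PoeDosage:
    """Resolve the parental origin of the offspring's minor allele(s).

    Parameters
    ----------
    mother_count, offspring_count : minor-allele counts in {0, 1, 2}, or
        NaN/None for missing (-> uninformative).
    maf : the SNP's minor allele frequency in (0, 0.5], used only for the
        ambiguous double-heterozygote row.
    """
    if not (0.0 < maf <= 0.5):
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    m = None if mother_count is None or (isinstance(mother_count, float) and np.isnan(mother_count)) else int(mother_count)
    o = None if offspring_count is None or (isinstance(offspring_count, float) and np.isnan(offspring_count)) else int(offspring_count)
    if m is None or o is None:
        return PoeDosage(np.nan, np.nan, Category.UNINFORMATIVE)
    if m not in (0, 1, 2) or o not in (0, 1, 2):
        raise ValueError(f"genotype counts must be 0, 1 or 2; got ({m}, {o})")
    if (m, o) in ((0, 2), (2, 0)):
        return PoeDosage(np.nan, np.nan, Category.INCONSISTENT)
    if (m, o) == (1, 1):
        return PoeDosage(1.0 - maf, maf, Category.AMBIGUOUS)
    # the maternal allele is forced by the mother's genotype
    if o == 0:
        return PoeDosage(0.0, 0.0, Category.UNAMBIGUOUS)
    if o == 2:
        return PoeDosage(1.0, 1.0, Category.UNAMBIGUOUS)
    # offspring heterozygous, mother homozygous: origin forced
    g_md = 1.0 if m == 2 else 0.0
    return PoeDosage(g_md, 1.0 - g_md, Category.UNAMBIGUOUS)


def dosage_columns(
    mother: np.ndarray, offspring: np.ndarray, maf: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized dosage: returns (g_md, g_pd, category codes).

    Category codes follow :class:`Category` values as a string array.
    Non-informative and inconsistent entries carry NaN dosages.
    """
    m = np.asarray(mother, dtype=float)
    o = np.asarray(offspring, dtype=float)
    g_md = np.full(m.shape, np.nan)
    g_pd = np.full(m.shape, np.nan)
    cat = np.full(m.shape, Category.UNINFORMATIVE.value, dtype=object)

    known = ~np.isnan(m) & ~np.isnan(o)
    bad = known & (((m == 0) & (o == 2)) | ((m == 2) & (o == 0)))
    cat[bad] = Category.INCONSISTENT.value
    ok = known & ~bad

    amb = ok & (m == 1) & (o == 1)
    g_md[amb], g_pd[amb] = 1.0 - maf, maf
    cat[amb] = Category.AMBIGUOUS.value

    una = ok & ~amb
    g_md[una & (o == 0)] = 0.0
    g_pd[una & (o == 0)] = 0.0
    g_md[una & (o == 2)] = 1.0
    g_pd[una & (o == 2)] = 1.0
    het = una & (o == 1)
    g_md[het] = np.where(m[het] == 2, 1.0, 0.0)
    g_pd[het] = 1.0 - g_md[het]
    cat[una] = Category.UNAMBIGUOUS.value
    return g_md, g_pd, cat.astype(str)


def build_dosage_matrix(
    table: GenotypeTable,
    maf: pd.Series | None = None,
    mode: str = "dosage",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dosage columns for every mother-offspring pair and SNP.

    Parameters
    ----------
    table : QC'd genotype table with resolved mother-offspring links.
    maf : per-SNP minor allele frequency; defaults to the mothers-only
        estimate from ``table``, frozen before construction.
    mode : ``"dosage"`` assigns (1-MAF, MAF) to ambiguous double
        heterozygotes; ``"exclude_ambiguous"`` drops them (their dosages
        are set to NaN so they fall out of the analysis set for that SNP).

    Returns
    -------
    matrix : long DataFrame with columns subject_id, snp_id, g_md, g_pd,
        category — one row per pair per SNP.
    counts : per-SNP category counts (columns are category names).
    """
    if mode not in ("dosage", "exclude_ambiguous"):
        raise ValueError(f"unknown mode {mode!r}")
    if maf is None:
        maf = estimate_maf(table, roles=("mother",))
    pairs = table.pairs()
    off = table.calls.loc[pairs.index]
    mot = table.calls.loc[pairs["mother_id"]].set_axis(pairs.index, axis=0)

    frames = []
    for snp in table.snp_ids:
        g_md, g_pd, cat = dosage_columns(mot[snp].to_numpy(), off[snp].to_numpy(), float(maf[snp]))
        if mode == "exclude_ambiguous":
            drop = cat == Category.AMBIGUOUS.value
            g_md = np.where(drop, np.nan, g_md)
            g_pd = np.where(drop, np.nan, g_pd)
        frames.append(pd.DataFrame({
            "subject_id": pairs.index,
            "snp_id": snp,
            "g_md": g_md,
            "g_pd": g_pd,
            "category": cat,
        }))
    matrix = pd.concat(frames, ignore_index=True)
    counts = (
        matrix.pivot_table(index="snp_id", columns="category", values="subject_id",
                           aggfunc="count", fill_value=0)
        .reindex(columns=[c.value for c in Category], fill_value=0)
    )
    counts.columns.name = None
    return matrix, counts


class PoeDosageEncoder(TransformerMixin, BaseEstimator):
    """Transformer mapping (mother, offspring) counts to (g_md, g_pd).

    Fits the minor allele frequency from the mother column (unless ``maf``
    is given) and transforms two-column genotype input into the
    parental-origin dosage pair. Non-informative or Mendelian-inconsistent
    rows transform to NaN.

    Parameters
    ----------
    maf : fixed MAF to use; if None it is estimated from the mothers seen
        during :meth:`fit`.
    mode : "dosage" or "exclude_ambiguous" (ambiguous rows -> NaN).

    Attributes
    ----------
    maf_ : the frequency used by :meth:`transform`.
    category_counts_ : dict of category -> count from the fitted data.
    """

    def __init__(self, maf: float | None = None, mode: str = "dosage"):
        self.maf = maf
        self.mode = mode

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: mother and offspring counts")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        if self.mode not in ("dosage", "exclude_ambiguous"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.maf is not None:
            self.maf_ = float(self.maf)
        else:
            mothers = X[:, 0]
            mothers = mothers[~np.isnan(mothers)]
            if mothers.size == 0:
                raise ValueError("cannot estimate MAF: all mother calls missing")
            f = mothers.sum() / (2.0 * mothers.size)
            self.maf_ = float(min(f, 1.0 - f))
        _, _, cat = dosage_columns(X[:, 0], X[:, 1], self.maf_)
        values, n = np.unique(cat, return_counts=True)
        self.category_counts_ = dict(zip(values.tolist(), n.tolist()))
        self.n_features_in_ = 2
        return self

    def transform(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "maf_")
        X = self._validate(X)
        g_md, g_pd, cat = dosage_columns(X[:, 0], X[:, 1], self.maf_)
        if self.mode == "exclude_ambiguous":
            amb = cat == Category.AMBIGUOUS.value
            g_md = np.where(amb, np.nan, g_md)
            g_pd = np.where(amb, np.nan, g_pd)
        return np.column_stack([g_md, g_pd])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(["g_md", "g_pd"], dtype=object)
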