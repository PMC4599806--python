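"""Genotype/phenotype tables for mother-offspring pair studies, QC, traits.

Genotypes are biallelic SNPs coded as minor-allele counts (0/1/2, missing
allowed). Subjects carry a role (mother, offspring, father) and offspring
link to their mother by id. QC applies the standard family-study filters:
per-SNP call rate, Hardy-Weinberg equilibrium among founders, and the
mother-offspring Mendelian-inconsistency rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ROLES = ("mother", "offspring", "father")

#: Recognized missing-genotype tokens in delimited input.
MISSING_TOKENS = {"", ".", "NA", "NN", "nan", "None", "00", "--", "0/0", "N/N"}


class GenotypeParseError(ValueError):
    """Raised for malformed genotype input; message names the line."""


class UndefinedMafError(ValueError):
    """Raised when a SNP has no non-missing calls in the MAF subset."""


@dataclass
class SnpRecord:
    """One biallelic SNP with its allele orientation and frequency."""

    snp_id: str
    gene: str = ""
    chromosome: str = ""
    position: int = 0
    minor_allele: str = "a"
    major_allele: str = "A"
    maf: float | None = None

    def __post_init__(self):
        if self.minor_allele == self.major_allele:
            raise ValueError(f"{self.snp_id}: minor and major allele identical")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf {self.maf} outside [0, 0.5]")


@dataclass
class GenotypeTable:
    """SNP-major genotype calls for a set of linked family members.

    Attributes
    ----------
    snps : DataFrame indexed by snp_id with columns gene, chromosome,
        position, minor_allele, major_allele, maf.
    subjects : DataFrame indexed by subject_id with columns role,
        mother_id, father_id (missing links as NaN/empty).
    calls : DataFrame (subjects x snps) of minor-allele counts as floats;
        NaN marks a missing call.
    """

    snps: pd.DataFrame
    subjects: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self):
        if self.subjects.index.has_duplicates:
            dup = self.subjects.index[self.subjects.index.duplicated()][0]
            raise GenotypeParseError(f"duplicate subject id: {dup}")
        bad = set(self.subjects["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown subject role(s): {sorted(bad)}")
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("calls must be 0, 1, 2 or missing")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps.index)

    def pairs(self) -> pd.DataFrame:
        """Mother-offspring links: one row per offspring with a known mother."""
        off = self.subjects[self.subjects["role"] == "offspring"]
        out = off[["mother_id"]].dropna()
        missing = out.index[~out["mother_id"].isin(self.subjects.index)]
        if len(missing):
            raise ValueError(
                f"offspring {missing[0]!r} links to an unknown mother id"
            )
        return out

    def subset_snps(self, keep: Sequence[str]) -> "GenotypeTable":
        keep = [s for s in self.snp_ids if s in set(keep)]
        return GenotypeTable(
            snps=self.snps.loc[keep].copy(),
            subjects=self.subjects.copy(),
            calls=self.calls[keep].copy(),
        )

    def role_calls(self, roles: Iterable[str]) -> pd.DataFrame:
        ids = self.subjects.index[self.subjects["role"].isin(set(roles))]
        return self.calls.loc[ids]


@dataclass
class PhenotypeTable:
    """Per-offspring traits, repeats, medication flags, ancestry, weights.

    One row per offspring. Recognized columns include raw trait values and
    repeats (e.g. ``wc_1``/``wc_2``, ``sbp_1``..``sbp_3``), medication flags
    (``diabetes_med``, ``lipid_med``, ``bp_med``), grandparental origin
    codes ``gp_origin_1``..``gp_origin_4`` and ``sampling_prob``.
    """

    data: pd.DataFrame

    def __post_init__(self):
        if "sampling_prob" in self.data.columns:
            p = self.data["sampling_prob"].dropna()
            if (p <= 0).any() or (p > 1).any():
                raise ValueError("sampling probabilities must lie in (0, 1]")

    @property
    def weights(self) -> pd.Series:
        """Inverse-probability sampling weights (1 where no design given)."""
        if "sampling_prob" in self.data.columns:
            return 1.0 / self.data["sampling_prob"]
        return pd.Series(1.0, index=self.data.index)


# --------------------------------------------------------------------------
# trait preparation


@dataclass(frozen=True)
class TraitSpec:
    name: str
    columns: tuple[str, ...]
    log: bool = False
    medication: str | None = None
    units: str = ""


#: The cardio-metabolic trait registry: repeats averaged, insulin and
#: triglycerides natural-log transformed (mean on the raw scale, then log),
#: medication exclusions per trait family.
TRAITS: dict[str, TraitSpec] = {
    "bmi": TraitSpec("bmi", ("bmi",), units="kg/m^2"),
    "wc": TraitSpec("wc", ("wc_1", "wc_2"), units="cm"),
    "glucose": TraitSpec("glucose", ("glucose",), medication="diabetes_med", units="mg/dL"),
    "insulin": TraitSpec("insulin", ("insulin_1", "insulin_2"), log=True,
                         medication="diabetes_med", units="ln mU/mL"),
    "ldl": TraitSpec("ldl", ("ldl",), medication="lipid_med", units="mmol/L"),
    "hdl": TraitSpec("hdl", ("hdl",), medication="lipid_med", units="mmol/L"),
    "tc": TraitSpec("tc", ("tc",), medication="lipid_med", units="mmol/L"),
    "tg": TraitSpec("tg", ("tg",), log=True, medication="lipid_med", units="ln mmol/L"),
    "sbp": TraitSpec("sbp", ("sbp_1", "sbp_2", "sbp_3"), medication="bp_med", units="mmHg"),
    "dbp": TraitSpec("dbp", ("dbp_1", "dbp_2", "dbp_3"), medication="bp_med", units="mmHg"),
}


def prepare_phenotypes(
    raw: PhenotypeTable, trait: str
) -> tuple[pd.Series, pd.DataFrame]:
    """Build the analysis-ready trait vector and an exclusion log.

    Repeated measurements are averaged on the raw scale; log-transformed
    traits (insulin, triglycerides) are logged after averaging. Subjects on
    the trait-relevant medication are excluded and logged, as are subjects
    with missing or non-positive-before-log values.

    Returns
    -------
    values : Series of prepared trait values indexed by subject id.
    exclusions : DataFrame with columns subject_id, reason.
    """
    if trait not in TRAITS:
        raise KeyError(f"unrecognized trait {trait!r}; known: {sorted(TRAITS)}")
    spec = TRAITS[trait]
    df = raw.data
    # fall back to a single unnumbered column if repeats are absent
    cols = [c for c in spec.columns if c in df.columns]
    if not cols and trait in df.columns:
        cols = [trait]
    if not cols:
        raise KeyError(f"no columns for trait {trait!r} in phenotype table")

    excluded: list[tuple[str, str]] = []
    keep = pd.Series(True, index=df.index)

    if spec.medication is not None and spec.medication in df.columns:
        flagged = df[spec.medication].fillna(0).astype(bool)
        for sid in df.index[flagged]:
            excluded.append((sid, f"medication:{spec.medication}"))
        keep &= ~flagged

    vals = df[cols].mean(axis=1, skipna=False)
    missing = vals.isna() & keep
    for sid in df.index[missing]:
        excluded.append((sid, "missing"))
    keep &= ~vals.isna()

    if spec.log:
        nonpos = (vals <= 0) & keep
        for sid in df.index[nonpos]:
            excluded.append((sid, "nonpositive_before_log"))
        keep &= vals > 0
        vals = np.log(vals.where(vals > 0))

    out = vals[keep]
    out.name = trait
    log = pd.DataFrame(excluded, columns=["subject_id", "reason"])
    return out, log


# --------------------------------------------------------------------------
# allele frequency


def coded_allele_frequency(
    table: GenotypeTable, roles: Iterable[str] = ("mother",)
) -> pd.Series:
    """Raw frequency of the currently-coded allele, before re-orientation."""
    calls = table.role_calls(roles)
    n = calls.notna().sum(axis=0)
    if (n == 0).any():
        bad = list(n.index[n == 0])
        raise UndefinedMafError(f"no non-missing calls for SNP(s): {bad}")
    return calls.sum(axis=0, skipna=True) / (2.0 * n)


def estimate_maf(
    table: GenotypeTable, roles: Iterable[str] = ("mother",)
) -> pd.Series:
    """Minor allele frequency per SNP from the given subject roles.

    By default only mothers (founders) contribute, which avoids counting
    transmitted alleles twice; pass ``roles=("mother", "offspring")`` for a
    pooled estimate. Frequencies above 0.5 are re-oriented (the coded
    allele is not actually minor), so the result is always in [0, 0.5].
    """
    f = coded_allele_frequency(table, roles)
    return np.minimum(f, 1.0 - f)


def orient_minor_alleles(
    table: GenotypeTable, roles: Iterable[str] = ("mother",)
) -> tuple[GenotypeTable, pd.Series]:
    """Flip SNPs whose coded-allele frequency exceeds 0.5.

    Flipping recodes counts k -> 2 - k and swaps the allele labels, then
    stores the (re-estimated) MAF on the snps frame. Returns the corrected
    table and a boolean Series of which SNPs were flipped.
    """
    f = coded_allele_frequency(table, roles)
    flipped = f > 0.5
    calls = table.calls.copy()
    snps = table.snps.copy()
    for snp in f.index[flipped]:
        calls[snp] = 2.0 - calls[snp]
        minor, major = snps.at[snp, "minor_allele"], snps.at[snp, "major_allele"]
        snps.at[snp, "minor_allele"] = major
        snps.at[snp, "major_allele"] = minor
    snps["maf"] = np.minimum(f, 1.0 - f)
    return GenotypeTable(snps=snps, subjects=table.subjects.copy(), calls=calls), flipped


# --------------------------------------------------------------------------
# QC


def hwe_test(genotype_counts: Sequence[int]) -> tuple[float, float]:
    """1-df Hardy-Weinberg chi-square goodness-of-fit test.

    ``genotype_counts`` is (n_AA, n_Aa, n_aa); the allele frequency is
    estimated from the sample and observed cells are compared with the
    p^2, 2pq, q^2 expectations. A monomorphic SNP returns (0, 1).
    """
    n_aa_maj, n_het, n_aa_min = (int(c) for c in genotype_counts)
    n = n_aa_maj + n_het + n_aa_min
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    q = (n_het + 2 * n_aa_min) / (2.0 * n)
    p = 1.0 - q
    if q == 0.0 or p == 0.0:
        return 0.0, 1.0
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([n_aa_maj, n_het, n_aa_min], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def genotype_counts(calls: pd.Series) -> tuple[int, int, int]:
    """Tally (n_hom_major, n_het, n_hom_minor) ignoring missing calls."""
    v = calls.dropna().to_numpy()
    return int((v == 0).sum()), int((v == 1).sum()), int((v == 2).sum())


def mendel_inconsistency(table: GenotypeTable) -> pd.Series:
    """Per-SNP mother-offspring Mendelian-inconsistency rate.

    With only one parent observed, the only impossible combinations are
    (mother 0, offspring 2) and (mother 2, offspring 0). Pairs with a
    missing call at the SNP are excluded from the denominator.
    """
    pairs = table.pairs()
    off = table.calls.loc[pairs.index]
    mot = table.calls.loc[pairs["mother_id"]].set_axis(pairs.index, axis=0)
    informative = off.notna() & mot.notna()
    inconsistent = ((mot == 0) & (off == 2)) | ((mot == 2) & (off == 0))
    denom = informative.sum(axis=0)
    rate = inconsistent.sum(axis=0) / denom.where(denom > 0)
    return rate.fillna(0.0)


@dataclass(frozen=True)
class QcThresholds:
    """Exclusion thresholds; violations must be strict to exclude.

    A SNP fails iff call_rate < min_call_rate, or HWE p < hwe_alpha / n_snps
    (Bonferroni over the SNPs present at entry; set ``hwe_bonferroni=False``
    to use ``hwe_alpha`` directly), or Mendelian-inconsistency rate >
    max_mendel_rate. A SNP sitting exactly on a threshold is retained.
    """

    min_call_rate: float = 0.95
    hwe_alpha: float = 0.05
    hwe_bonferroni: bool = True
    max_mendel_rate: float = 0.005


@dataclass
class QCReport:
    """Per-SNP QC metrics with pass/fail flags and the reasons applied."""

    table: pd.DataFrame
    thresholds: QcThresholds

    @property
    def passed(self) -> list[str]:
        return list(self.table.index[self.table["pass"]])

    @property
    def failed(self) -> list[str]:
        return list(self.table.index[~self.table["pass"]])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="snp_id")


def apply_qc(
    table: GenotypeTable,
    thresholds: QcThresholds | None = None,
    hwe_roles: Iterable[str] = ("mother",),
) -> tuple[GenotypeTable, QCReport]:
    """Apply call-rate, HWE and Mendelian filters; return the kept table.

    HWE is tested among founders (mothers by default) so that transmitted
    alleles are not double-counted. The HWE Bonferroni denominator is the
    number of SNPs present at entry, which makes the filter idempotent.
    """
    th = thresholds or QcThresholds()
    n_snps = len(table.snp_ids)
    hwe_cut = th.hwe_alpha / n_snps if th.hwe_bonferroni else th.hwe_alpha

    call_rate = table.calls.notna().mean(axis=0)
    mendel = mendel_inconsistency(table)
    founder_calls = table.role_calls(hwe_roles)
    rows = []
    for snp in table.snp_ids:
        counts = genotype_counts(founder_calls[snp])
        if sum(counts) == 0:
            chi2, p = 0.0, 1.0
            maf = np.nan
        else:
            chi2, p = hwe_test(counts)
            maf = (counts[1] + 2 * counts[2]) / (2.0 * sum(counts))
            maf = min(maf, 1.0 - maf)
        reasons = []
        if call_rate[snp] < th.min_call_rate:
            reasons.append(f"call_rate<{th.min_call_rate}")
        if p < hwe_cut:
            reasons.append(f"hwe_p<{hwe_cut:.3g}")
        if mendel[snp] > th.max_mendel_rate:
            reasons.append(f"mendel_rate>{th.max_mendel_rate}")
        rows.append(
            dict(snp_id=snp, call_rate=call_rate[snp], hwe_chi2=chi2, hwe_p=p,
                 mendel_rate=mendel[snp], maf=maf,
                 **{"pass": not reasons}, reasons=";".join(reasons))
        )
    report = pd.DataFrame(rows).set_index("snp_id")
    kept = table.subset_snps(list(report.index[report["pass"]]))
    if not kept.snp_ids:
        warnings.warn("all SNPs failed QC; returning an empty table", stacklevel=2)
    return kept, QCReport(table=report, thresholds=th)


# --------------------------------------------------------------------------
# I/O


@dataclass(frozen=True)
class Dialect:
    """Column-role mapping for delimited genotype input.

    ``fmt`` is one of ``counts`` (wide, minor-allele counts), ``alleles``
    (wide, two-character allele pairs such as ``AG``; orientation inferred
    from allele tallies) or ``ped`` (white-space PED with a companion .map,
    allele 0 = missing).
    """

    fmt: str = "counts"
    subject_col: str = "subject_id"
    role_col: str = "role"
    mother_col: str = "mother_id"
    father_col: str = "father_id"
    sep: str | None = None
    map_path: str | None = None


def _empty_snp_frame(snp_ids: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": "",
            "chromosome": "",
            "position": 0,
            "minor_allele": "a",
            "major_allele": "A",
            "maf": np.nan,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )


def read_genotypes(path, dialect: Dialect | None = None) -> GenotypeTable:
    """Read a genotype table; calls come back as minor-allele counts.

    Unknown genotype codes become missing; structurally malformed rows (or
    duplicate subject ids) raise :class:`GenotypeParseError` naming the line.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect.fmt == "ped":
        return _read_ped(path, dialect)
    sep = dialect.sep
    if sep is None:
        head = path.read_text().splitlines()[0] if path.stat().st_size else ""
        sep = "\t" if "\t" in head else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in (dialect.subject_col, dialect.role_col):
        if col not in df.columns:
            raise GenotypeParseError(f"missing required column {col!r}")
    meta_cols = {dialect.subject_col, dialect.role_col, dialect.mother_col,
                 dialect.father_col}
    snp_cols = [c for c in df.columns if c not in meta_cols]
    if df[dialect.subject_col].duplicated().any():
        dup = df[dialect.subject_col][df[dialect.subject_col].duplicated()].iloc[0]
        raise GenotypeParseError(f"duplicate subject id: {dup}")

    subjects = pd.DataFrame(
        {
            "role": df[dialect.role_col].str.lower().values,
            "mother_id": (df[dialect.mother_col].where(df[dialect.mother_col] != "").values
                          if dialect.mother_col in df.columns else np.nan),
            "father_id": (df[dialect.father_col].where(df[dialect.father_col] != "").values
                          if dialect.father_col in df.columns else np.nan),
        },
        index=pd.Index(df[dialect.subject_col].values, name="subject_id"),
    )

    if dialect.fmt == "counts":
        calls = pd.DataFrame(index=subjects.index, columns=snp_cols, dtype=float)
        for snp in snp_cols:
            col = df[snp].str.strip()
            out = np.full(len(col), np.nan)
            for i, tok in enumerate(col):
                if tok in MISSING_TOKENS:
                    continue
                try:
                    v = float(tok)
                except ValueError as exc:
                    raise GenotypeParseError(
                        f"line {i + 2}: bad genotype code {tok!r} for {snp}"
                    ) from exc
                if v not in (0.0, 1.0, 2.0):
                    continue  # unknown numeric code -> missing
                out[i] = v
            calls[snp] = out
        table = GenotypeTable(_empty_snp_frame(snp_cols), subjects, calls)
        return table
    if dialect.fmt == "alleles":
        return _recode_alleles(df, subjects, snp_cols)
    raise ValueError(f"unknown genotype dialect {dialect.fmt!r}")


def _split_allele_pair(tok: str, line: int, snp: str) -> tuple[str, str] | None:
    tok = tok.strip()
    if tok in MISSING_TOKENS:
        return None
    tok = tok.replace("/", "").replace("|", "")
    if len(tok) != 2 or not tok.isalpha():
        raise GenotypeParseError(f"line {line}: bad allele pair {tok!r} for {snp}")
    a, b = tok[0].upper(), tok[1].upper()
    if a == "N" or b == "N":
        return None
    return a, b


def _recode_alleles(df, subjects, snp_cols) -> GenotypeTable:
    """Recode allele-pair strings to minor-allele counts (minor = rarer)."""
    snps = _empty_snp_frame(snp_cols)
    calls = pd.DataFrame(index=subjects.index, columns=snp_cols, dtype=float)
    for snp in snp_cols:
        pairs = [
            _split_allele_pair(tok, i + 2, snp) for i, tok in enumerate(df[snp])
        ]
        tally: dict[str, int] = {}
        for pr in pairs:
            if pr:
                for al in pr:
                    tally[al] = tally.get(al, 0) + 1
        if len(tally) > 2:
            raise GenotypeParseError(f"SNP {snp} has more than two alleles: {sorted(tally)}")
        if not tally:
            snps.loc[snp, ["minor_allele", "major_allele"]] = ["a", "A"]
            calls[snp] = np.nan
            continue
        # minor = less frequent allele; deterministic tie-break on name
        alleles = sorted(tally, key=lambda al: (tally[al], al))
        if len(alleles) == 1:
            # monomorphic: the observed allele is major, minor unseen
            major = alleles[0]
            minor = next(x for x in "abcd" if x.upper() != major.upper())
        else:
            minor, major = alleles[0], alleles[1]
        snps.at[snp, "minor_allele"] = minor
        snps.at[snp, "major_allele"] = major
        out = np.full(len(pairs), np.nan)
        for i, pr in enumerate(pairs):
            if pr:
                out[i] = (pr[0] == minor) + (pr[1] == minor)
        calls[snp] = out
    return GenotypeTable(snps, subjects, calls)


def _read_ped(path: Path, dialect: Dialect) -> GenotypeTable:
    """White-space PED with companion MAP; allele code 0 means missing."""
    map_path = Path(dialect.map_path) if dialect.map_path else path.with_suffix(".map")
    if not map_path.exists():
        raise FileNotFoundError(map_path)
    snp_meta = []
    for line in map_path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise GenotypeParseError(f"map line too short: {line!r}")
        snp_meta.append((parts[1], parts[0], int(parts[3])))
    snp_ids = [m[0] for m in snp_meta]

    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * len(snp_ids):
            raise GenotypeParseError(
                f"line {lineno}: expected {6 + 2 * len(snp_ids)} fields, got {len(parts)}"
            )
        rows.append((lineno, parts))

    ids = [p[1] for _, p in rows]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise GenotypeParseError(f"duplicate subject id: {dup}")
    mothers = {p[3] for _, p in rows if p[3] != "0"}
    fathers = {p[2] for _, p in rows if p[2] != "0"}

    roles, mother_ids, father_ids = [], [], []
    for _, p in rows:
        iid, pat, mat, sex = p[1], p[2], p[3], p[4]
        if iid in mothers:
            roles.append("mother")
        elif iid in fathers:
            roles.append("father")
        elif mat != "0":
            roles.append("offspring")
        else:
            roles.append("mother" if sex == "2" else "father")
        mother_ids.append(mat if mat != "0" else np.nan)
        father_ids.append(pat if pat != "0" else np.nan)
    subjects = pd.DataFrame(
        {"role": roles, "mother_id": mother_ids, "father_id": father_ids},
        index=pd.Index(ids, name="subject_id"),
    )

    snps = _empty_snp_frame(snp_ids)
    snps["chromosome"] = [m[1] for m in snp_meta]
    snps["position"] = [m[2] for m in snp_meta]
    calls = pd.DataFrame(index=subjects.index, columns=snp_ids, dtype=float)

    # first pass: tally alleles per SNP to pick the minor allele
    geno = {snp: [] for snp in snp_ids}
    for _, p in rows:
        for j, snp in enumerate(snp_ids):
            a, b = p[6 + 2 * j], p[7 + 2 * j]
            geno[snp].append(None if a == "0" or b == "0" else (a, b))
    for snp in snp_ids:
        tally: dict[str, int] = {}
        for pr in geno[snp]:
            if pr:
                for al in pr:
                    tally[al] = tally.get(al, 0) + 1
        if len(tally) > 2:
            raise GenotypeParseError(f"SNP {snp} has more than two alleles")
        if tally:
            alleles = sorted(tally, key=lambda al: (tally[al], al))
            if len(alleles) == 1:
                major = alleles[0]
                minor = next(x for x in "abcd" if x.upper() != major.upper())
            else:
                minor, major = alleles[0], alleles[1]
            snps.at[snp, "minor_allele"] = minor
            snps.at[snp, "major_allele"] = major
            calls[snp] = [
                np.nan if pr is None else float((pr[0] == minor) + (pr[1] == minor))
                for pr in geno[snp]
            ]
        else:
            calls[snp] = np.nan
    return GenotypeTable(snps, subjects, calls)


def write_genotypes(table: GenotypeTable, path) -> None:
    """Write the wide ``counts`` dialect (tab-separated); round-trips reads."""
    df = table.subjects.reset_index()[["subject_id", "role", "mother_id", "father_id"]]
    calls = table.calls.reset_index(drop=True)
    out = pd.concat([df, calls], axis=1)
    for snp in table.snp_ids:
        out[snp] = out[snp].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_phenotypes(path, sep: str | None = None) -> PhenotypeTable:
    """Read a delimited phenotype/covariate table, one row per offspring."""
    path = Path(path)
    if sep is None:
        head = path.read_text().splitlines()[0] if path.stat().st_size else ""
        sep = "\t" if "\t" in head else ","
    df = pd.read_csv(path, sep=sep)
    if "subject_id" in df.columns:
        df = df.set_index("subject_id")
    df.index = df.index.astype(str)
    return PhenotypeTable(df)
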