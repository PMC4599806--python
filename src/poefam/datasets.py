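"""Bundled per-study summary statistics for the APOB rs1367117 analyses.

The package ships the published per-study association summaries (beta, SE,
two-sided p, proband count) for the APOB missense variant rs1367117 across
the four contributing family studies — the mother-offspring discovery
cohort (JPS) and the three extended-pedigree replication studies (FHS,
FamHS, ERF) — for both the parental-origin model (maternally- and
paternally-derived effects) and the additive genotype model. These rows
are meta-analysis *inputs*; combined estimates are always recomputed by
:mod:`poefam.meta`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .meta import StudySummary

#: MAF of rs1367117 in each contributing study.
APOB_MAF = {"JPS": 0.20, "FHS": 0.31, "FamHS": 0.34, "ERF": 0.31}

#: SNPs genotyped per candidate gene in the discovery panel.
GENE_SNP_COUNTS = {
    "APOB": 10, "CDKN2A": 5, "CDKN2B": 4, "FTO": 2, "GCK": 5, "HNF4A": 9,
    "IGF1": 10, "IRS1": 1, "LPL": 11, "MC4R": 1, "MTHFR": 9, "POMC": 4,
    "PPARG": 13, "PSRC1": 3, "TCF1": 8, "TCF2": 22, "TCF7L2": 42, "TUB": 23,
}

#: Total SNPs screened in discovery (Bonferroni denominator for replication).
N_DISCOVERY_SNPS = 182


def _load(name: str) -> pd.DataFrame:
    with resources.files("poefam.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def apob_poe_summaries() -> pd.DataFrame:
    """Per-study parental-origin summaries: trait, origin, study, n, beta, se, p."""
    return _load("apob_rs1367117_poe.csv")


def apob_genotype_summaries() -> pd.DataFrame:
    """Per-study additive-genotype summaries: trait, study, n, beta, se, p."""
    return _load("apob_rs1367117_genotype.csv")


def study_summaries(
    trait: str, origin: str | None = "maternal", genotype: bool = False
) -> list[StudySummary]:
    """The bundled rows for one trait as :class:`StudySummary` objects.

    ``genotype=True`` selects the additive-model table (``origin`` ignored).
    """
    df = apob_genotype_summaries() if genotype else apob_poe_summaries()
    df = df[df["trait"] == trait]
    if not genotype:
        df = df[df["origin"] == origin]
    if df.empty:
        raise KeyError(f"no bundled rows for trait {trait!r}")
    return [
        StudySummary(study=r.study, beta=r.beta, se=r.se, p_value=r.p, n=int(r.n))
        for r in df.itertuples()
    ]
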