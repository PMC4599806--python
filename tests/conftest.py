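import numpy as np
import pandas as pd
import pytest

from poefam.families import GenotypeTable, PhenotypeTable
from poefam.simulate import SimConfig, SnpSpec, simulate_study


def make_table(mother_counts, offspring_counts, snp_ids=None):
    """Build a mother-offspring GenotypeTable from per-SNP count arrays.

    ``mother_counts``/``offspring_counts``: dict snp_id -> list of counts
    (np.nan allowed), aligned across SNPs; pair i links O{i} to M{i}.
    """
    snp_ids = snp_ids or list(mother_counts)
    n = len(next(iter(mother_counts.values())))
    mothers = [f"M{i}" for i in range(n)]
    offspring = [f"O{i}" for i in range(n)]
    subjects = pd.DataFrame(
        {
            "role": ["mother"] * n + ["offspring"] * n,
            "mother_id": [np.nan] * n + mothers,
            "father_id": np.nan,
        },
        index=pd.Index(mothers + offspring, name="subject_id"),
    )
    calls = pd.DataFrame(
        {
            s: list(map(float, mother_counts[s])) + list(map(float, offspring_counts[s]))
            for s in snp_ids
        },
        index=subjects.index,
    )
    snps = pd.DataFrame(
        {
            "gene": "", "chromosome": "1", "position": 0,
            "minor_allele": "a", "major_allele": "A", "maf": np.nan,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeTable(snps=snps, subjects=subjects, calls=calls)


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (n=1235, MAF 0.2, maternal-only effect)."""
    return simulate_study(SimConfig(seed=11))


@pytest.fixture(scope="session")
def trio_study():
    """A study with fathers retained for truth-based checks."""
    return simulate_study(SimConfig(seed=12, hide_fathers=False))
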