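"""Synthetic nuclear-family studies with known parent-of-origin structure.

Families are mother-father-offspring trios: parental genotypes are drawn
i.i.d. from Hardy-Weinberg proportions at the configured MAF (random
mating), each parent transmits one allele uniformly at random (Mendelian
transmission), and the true parental origin of every offspring allele is
recorded. The phenotype follows the parental-origin mean model

    Y = b0 + b_MD * (true maternal minor count)
           + b_PD * (true paternal minor count) + g'Z + N(0, noise_sd)

with Z containing grandparental-ancestry proportions and sex. Hiding the
fathers produces the mother-offspring analysis view while the truth stays
sealed for evaluation, so the dosage estimator is always tested against an
independent generative process — the simulator never uses the dosage rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .families import GenotypeTable, PhenotypeTable, _empty_snp_frame
from .regression import REFERENCE_STRATUM, STRATA, ancestry_design


@dataclass(frozen=True)
class SnpSpec:
    """One simulated SNP: its MAF and true parental-origin effect sizes."""

    maf: float
    beta_md: float = 0.0
    beta_pd: float = 0.0
    snp_id: str | None = None

    def __post_init__(self):
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic mother-offspring study.

    Defaults emulate the discovery-study conditions: n = 1235 pairs, one
    SNP at MAF 0.2 with a maternal-only effect of 1.4 trait units (a
    BMI-scale effect), BMI-like intercept and residual noise (SD 4.5
    kg/m^2), nine ancestry strata and a Bernoulli(0.5) sex covariate.
    """

    n_pairs: int = 1235
    snps: tuple[SnpSpec, ...] = (SnpSpec(maf=0.2, beta_md=1.4, beta_pd=0.0),)
    beta0: float = 26.0
    sex_effect: float = 1.0
    stratum_effects: tuple[float, ...] | None = None  # one per stratum; reference ignored
    noise_sd: float = 4.5
    trait: str = "bmi"
    n_strata: int = 9
    stratum_probs: tuple[float, ...] | None = None
    stratum_mafs: tuple[float, ...] | None = None  # per-stratum MAF override
    sampling_design: tuple[tuple[float, float], ...] | None = None
    #: each (cohort fraction, inclusion probability); fractions must sum to 1
    hide_fathers: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.sampling_design is not None:
            fracs = [f for f, _ in self.sampling_design]
            probs = [p for _, p in self.sampling_design]
            if abs(sum(fracs) - 1.0) > 1e-9:
                raise ValueError("sampling_design fractions must sum to 1")
            if any(p <= 0 or p > 1 for p in probs):
                raise ValueError("inclusion probabilities must be in (0, 1]")

    def snp_ids(self) -> list[str]:
        return [s.snp_id or f"snp{i + 1}" for i, s in enumerate(self.snps)]


@dataclass
class SimulatedStudy:
    """A generated study: analysis view plus a sealed truth block.

    ``truth`` holds the true per-SNP maternal/paternal transmitted minor
    counts for every offspring, the father calls, and a copy of the true
    parameters; it is retained through :func:`hide_fathers` for evaluation
    only and is never consulted by the analysis code.
    """

    genotypes: GenotypeTable
    phenotypes: PhenotypeTable | None
    truth: dict
    config: SimConfig

    @property
    def offspring_ids(self) -> list[str]:
        sub = self.genotypes.subjects
        return list(sub.index[sub["role"] == "offspring"])


def simulate_genotypes(config: SimConfig) -> SimulatedStudy:
    """Draw trio genotypes under HWE, random mating and Mendelian transmission."""
    rng = np.random.default_rng(config.seed)
    n = config.n_pairs
    snp_ids = config.snp_ids()

    # ancestry strata: each family draws one stratum; all four grandparents
    # share it (the admixed option draws grandparents i.i.d. elsewhere)
    strata = list(STRATA[: config.n_strata])
    probs = config.stratum_probs or tuple(1.0 / len(strata) for _ in strata)
    stratum_idx = rng.choice(len(strata), size=n, p=np.asarray(probs) / np.sum(probs))

    mother_ids = [f"M{i:05d}" for i in range(n)]
    father_ids = [f"F{i:05d}" for i in range(n)]
    offspring_ids = [f"O{i:05d}" for i in range(n)]

    calls = {}
    g_md_true = {}
    g_pd_true = {}
    for j, spec in enumerate(config.snps):
        if config.stratum_mafs is not None:
            maf = np.asarray(config.stratum_mafs)[stratum_idx]
        else:
            maf = np.full(n, spec.maf)
        # parental genotypes as two independent allele draws each (HWE)
        m_alleles = rng.random((n, 2)) < maf[:, None]
        f_alleles = rng.random((n, 2)) < maf[:, None]
        mother = m_alleles.sum(axis=1).astype(float)
        father = f_alleles.sum(axis=1).astype(float)
        # each parent transmits one of its two alleles uniformly at random
        m_pick = rng.integers(2, size=n)
        f_pick = rng.integers(2, size=n)
        m_trans = m_alleles[np.arange(n), m_pick].astype(float)
        f_trans = f_alleles[np.arange(n), f_pick].astype(float)
        snp = snp_ids[j]
        calls[snp] = np.concatenate([mother, father, m_trans + f_trans])
        g_md_true[snp] = m_trans
        g_pd_true[snp] = f_trans

    subjects = pd.DataFrame(
        {
            "role": ["mother"] * n + ["father"] * n + ["offspring"] * n,
            "mother_id": [np.nan] * (2 * n) + mother_ids,
            "father_id": [np.nan] * (2 * n) + father_ids,
        },
        index=pd.Index(mother_ids + father_ids + offspring_ids, name="subject_id"),
    )
    snps = _empty_snp_frame(snp_ids)
    snps["maf"] = [s.maf for s in config.snps]
    table = GenotypeTable(
        snps=snps,
        subjects=subjects,
        calls=pd.DataFrame(calls, index=subjects.index),
    )
    truth = {
        "g_md": pd.DataFrame(g_md_true, index=pd.Index(offspring_ids, name="subject_id")),
        "g_pd": pd.DataFrame(g_pd_true, index=pd.Index(offspring_ids, name="subject_id")),
        "father_calls": table.calls.loc[father_ids].copy(),
        "stratum": pd.Series([strata[i] for i in stratum_idx],
                             index=offspring_ids, name="stratum"),
        "params": config,
    }
    return SimulatedStudy(genotypes=table, phenotypes=None, truth=truth, config=config)


def simulate_phenotype(study: SimulatedStudy, config: SimConfig | None = None) -> SimulatedStudy:
    """Generate the trait from the true transmissions (model-2 mean structure)."""
    config = config or study.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    off = study.offspring_ids
    n = len(off)
    strata = list(STRATA[: config.n_strata])

    sex = rng.integers(2, size=n)  # 1 = female
    stratum = study.truth["stratum"]
    origins = pd.DataFrame(
        {f"gp_origin_{k}": stratum.values for k in range(1, 5)}, index=off
    )
    anc = ancestry_design(origins)
    gamma = np.zeros(anc.shape[1])
    if config.stratum_effects is not None:
        non_ref = [s for s in STRATA if s != REFERENCE_STRATUM]
        for i, s in enumerate(strata):
            if s != REFERENCE_STRATUM:
                gamma[non_ref.index(s)] = config.stratum_effects[i]

    y = np.full(n, config.beta0, dtype=float)
    for snp, spec in zip(study.genotypes.snp_ids, config.snps):
        y += spec.beta_md * study.truth["g_md"][snp].to_numpy()
        y += spec.beta_pd * study.truth["g_pd"][snp].to_numpy()
    y += anc.to_numpy() @ gamma
    y += config.sex_effect * sex
    y += rng.normal(0.0, config.noise_sd, size=n)

    pheno = pd.DataFrame(index=pd.Index(off, name="subject_id"))
    pheno[config.trait] = y
    pheno["sex"] = sex
    for k in range(1, 5):
        pheno[f"gp_origin_{k}"] = stratum.values
    pheno["sampling_prob"] = 1.0

    if config.sampling_design is not None:
        # sampling strata are assigned by cohort fraction, independent of
        # ancestry (the oversampled design of the source cohort keyed on
        # maternal size and birth weight is emulated generically)
        rng_s = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
        fracs = np.array([f for f, _ in config.sampling_design])
        probs = np.array([p for _, p in config.sampling_design])
        s_idx = rng_s.choice(len(fracs), size=n, p=fracs)
        pheno["sampling_stratum"] = s_idx
        pheno["sampling_prob"] = probs[s_idx]

    return SimulatedStudy(
        genotypes=study.genotypes,
        phenotypes=PhenotypeTable(pheno),
        truth=study.truth,
        config=config,
    )


def stratified_sample(study: SimulatedStudy, seed_offset: int = 3) -> SimulatedStudy:
    """Thin the cohort by each subject's inclusion probability.

    Offspring are retained independently with their sampling stratum's
    probability; retained subjects carry weight = 1 / probability. Mothers
    and fathers of retained offspring are kept.
    """
    if study.phenotypes is None:
        raise ValueError("simulate_phenotype must run before sampling")
    pheno = study.phenotypes.data
    probs = pheno["sampling_prob"].to_numpy()
    if (probs <= 0).any():
        raise ValueError("inclusion probability must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([study.config.seed, seed_offset]))
    keep = rng.random(len(probs)) < probs
    kept_off = pheno.index[keep]

    sub = study.genotypes.subjects
    links = sub.loc[kept_off]
    wanted = set(kept_off)
    wanted.update(links["mother_id"].dropna())
    wanted.update(links["father_id"].dropna())
    keep_ids = [i for i in sub.index if i in wanted]

    geno = GenotypeTable(
        snps=study.genotypes.snps.copy(),
        subjects=sub.loc[keep_ids].copy(),
        calls=study.genotypes.calls.loc[keep_ids].copy(),
    )
    truth = dict(study.truth)
    truth["g_md"] = study.truth["g_md"].loc[kept_off]
    truth["g_pd"] = study.truth["g_pd"].loc[kept_off]
    return SimulatedStudy(
        genotypes=geno,
        phenotypes=PhenotypeTable(pheno.loc[kept_off].copy()),
        truth=truth,
        config=study.config,
    )


def hide_fathers(study: SimulatedStudy) -> SimulatedStudy:
    """Drop fathers from the analysis view; the sealed truth block stays.

    Idempotent: hiding twice equals hiding once.
    """
    sub = study.genotypes.subjects
    keep = sub.index[sub["role"] != "father"]
    geno = GenotypeTable(
        snps=study.genotypes.snps.copy(),
        subjects=sub.loc[keep].drop(columns=[]).copy(),
        calls=study.genotypes.calls.loc[keep].copy(),
    )
    geno.subjects.loc[geno.subjects["role"] == "offspring", "father_id"] = np.nan
    return SimulatedStudy(
        genotypes=geno, phenotypes=study.phenotypes,
        truth=study.truth, config=study.config,
    )


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Genotypes + phenotype + sampling + (optionally) father hiding."""
    study = simulate_phenotype(simulate_genotypes(config))
    if config.sampling_design is not None:
        study = stratified_sample(study)
    if config.hide_fathers:
        study = hide_fathers(study)
    return study
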