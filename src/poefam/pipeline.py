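"""End-to-end orchestration: simulate -> qc -> dosage -> scan -> permute -> meta.

Every stage is a plain function over the library; :func:`run_pipeline`
wires them together from a validated configuration, writes each stage's
output as a delimited table with a provenance header (config hash, seed,
package version), and is deterministic: identical config and seed produce
byte-identical result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dosage import build_dosage_matrix
from .families import (
    Dialect,
    GenotypeTable,
    PhenotypeTable,
    QcThresholds,
    apply_qc,
    estimate_maf,
    prepare_phenotypes,
    read_genotypes,
    read_phenotypes,
    write_genotypes,
)
from .meta import StudySummary, inverse_variance_meta, stouffer_meta
from .regression import ancestry_design, fit_additive, fit_poe
from .resampling import permute_poe
from .simulate import SimConfig, SnpSpec, simulate_study

log = logging.getLogger("poefam")


@dataclass
class PipelineConfig:
    """Validated pipeline settings; see the example config in the README."""

    out_dir: str
    seed: int
    traits: tuple[str, ...] = ("bmi",)
    mode: str = "dosage"
    genotypes: str | None = None
    phenotypes: str | None = None
    simulate: dict | None = None
    qc: dict = field(default_factory=dict)
    covariates: tuple[str, ...] = ("sex", "ancestry")
    weight_column: str | None = "sampling_prob"
    permute: dict | None = None
    meta_method: str = "both"
    meta_input: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must set a seed (stochastic stages require it)")
        for key in ("traits", "covariates"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _sim_config(cfg: PipelineConfig) -> SimConfig:
    sim = dict(cfg.simulate or {})
    snps = tuple(SnpSpec(**s) for s in sim.pop("snps", [{"maf": 0.2}]))
    sim.setdefault("seed", cfg.seed)
    if "sampling_design" in sim and sim["sampling_design"] is not None:
        sim["sampling_design"] = tuple(tuple(x) for x in sim["sampling_design"])
    return SimConfig(snps=snps, **sim)


def _write_table(df: pd.DataFrame, path: Path, header: str, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=index)


def _provenance(cfg: PipelineConfig) -> str:
    return (
        f"# poefam {__version__}\n"
        f"# config_hash {cfg.content_hash()}\n"
        f"# seed {cfg.seed}\n"
    )


def assemble_design(
    pheno: PhenotypeTable, covariates: Sequence[str]
) -> pd.DataFrame:
    """Covariate block Z from named roles: 'sex', 'ancestry', 'age', columns."""
    parts = []
    df = pheno.data
    for cov in covariates:
        if cov == "ancestry":
            parts.append(ancestry_design(df))
        elif cov in df.columns:
            parts.append(df[[cov]].astype(float))
        else:
            raise KeyError(f"covariate {cov!r} not in phenotype table")
    if not parts:
        return pd.DataFrame(index=df.index)
    return pd.concat(parts, axis=1)


def poe_scan(
    table: GenotypeTable,
    pheno: PhenotypeTable,
    traits: Sequence[str],
    mode: str = "dosage",
    covariates: Sequence[str] = ("sex", "ancestry"),
    use_weights: bool = True,
    adjust_bmi: bool = False,
) -> pd.DataFrame:
    """Fit models 1 and 2 for every SNP x trait; one result row each.

    The additive fit uses every pair with a non-missing offspring genotype;
    the parental-origin fit drops non-informative (missing-mother or
    Mendelian-inconsistent) pairs and, in ``exclude_ambiguous`` mode, the
    double heterozygotes — hence its smaller n.
    """
    maf = estimate_maf(table, roles=("mother",))
    matrix, counts = build_dosage_matrix(table, maf=maf, mode=mode)
    pairs = table.pairs()
    z_all = assemble_design(pheno, covariates)
    weights_all = pheno.weights if use_weights else pd.Series(1.0, index=pheno.data.index)

    rows = []
    for trait in traits:
        y_all, _ = prepare_phenotypes(pheno, trait)
        for snp in table.snp_ids:
            sub = matrix[matrix["snp_id"] == snp].set_index("subject_id")
            g_o = table.calls.loc[pairs.index, snp]

            # additive model: complete cases on trait, genotype, covariates
            idx = y_all.index.intersection(g_o.dropna().index)
            idx = idx.intersection(z_all.dropna().index if len(z_all.columns) else idx)
            add = fit_additive(
                y_all.loc[idx], g_o.loc[idx],
                z=z_all.loc[idx] if len(z_all.columns) else None,
                weights=weights_all.loc[idx].to_numpy(),
            )

            # parental-origin model: informative pairs only
            informative = sub.index[sub["g_md"].notna()]
            jdx = y_all.index.intersection(informative)
            jdx = jdx.intersection(z_all.dropna().index if len(z_all.columns) else jdx)
            zmat = z_all.loc[jdx] if len(z_all.columns) else None
            poe = fit_poe(
                y_all.loc[jdx], sub.loc[jdx, "g_md"], sub.loc[jdx, "g_pd"],
                z=zmat, weights=weights_all.loc[jdx].to_numpy(),
            )
            row = dict(
                snp_id=snp, trait=trait, maf=float(maf[snp]), mode=mode,
                n_genotype=add.n, beta_g=add.beta_g, se_g=add.se, p_g=add.p_value,
                n_poe=poe.n, beta_md=poe.beta_md, se_md=poe.se_md, p_md=poe.p_md,
                beta_pd=poe.beta_pd, se_pd=poe.se_pd, p_pd=poe.p_pd, f_p=poe.f_p,
                n_ambiguous=int(counts.loc[snp, "ambiguous"]),
                n_uninformative=int(counts.loc[snp, "uninformative"]),
                n_inconsistent=int(counts.loc[snp, "inconsistent"]),
            )
            if adjust_bmi and trait != "bmi":
                bmi_all, _ = prepare_phenotypes(pheno, "bmi")
                kdx = jdx.intersection(bmi_all.index)
                zk = z_all.loc[kdx] if len(z_all.columns) else None
                from .regression import adjust_for_bmi as _adj

                _, adj = _adj(
                    y_all.loc[kdx], sub.loc[kdx, "g_md"], sub.loc[kdx, "g_pd"],
                    zk, bmi_all.loc[kdx], weights=weights_all.loc[kdx].to_numpy(),
                    trait=trait,
                )
                row.update(p_md_bmi_adj=adj.p_md, f_p_bmi_adj=adj.f_p)
            rows.append(row)
    return pd.DataFrame(rows)


def run_meta(summaries: pd.DataFrame, method: str = "both") -> pd.DataFrame:
    """Combine a per-study summary table (grouped by trait/origin if present)."""
    keys = [c for c in ("trait", "origin") if c in summaries.columns]
    out = []
    groups = summaries.groupby(keys) if keys else [((), summaries)]
    for key, grp in groups:
        studies = [
            StudySummary(
                study=str(r.study), beta=float(r.beta), n=int(r.n),
                se=float(r.se) if "se" in grp.columns and pd.notna(r.se) else None,
                p_value=float(r.p) if "p" in grp.columns and pd.notna(r.p) else None,
            )
            for r in grp.itertuples()
        ]
        key = key if isinstance(key, tuple) else (key,)
        base = dict(zip(keys, key))
        if method in ("stouffer", "both"):
            res = stouffer_meta(studies)
            out.append({**base, "method": "stouffer", "beta": np.nan, "se": np.nan,
                        "z": res.z, "p": res.p_value, "n": res.n})
        if method in ("ivw", "both"):
            res = inverse_variance_meta(studies)
            out.append({**base, "method": "ivw", "beta": res.beta, "se": res.se,
                        "z": res.z, "p": res.p_value, "n": res.n})
    return pd.DataFrame(out)


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Execute the configured stages; returns the written file paths."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = _provenance(cfg)
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, index: bool = False):
        path = out_dir / f"{name}.tsv"
        _write_table(df, path, header, index)
        written[name] = path
        log.info("wrote %s (%d rows)", path, len(df))

    try:
        if cfg.simulate is not None:
            study = simulate_study(_sim_config(cfg))
            table, pheno = study.genotypes, study.phenotypes
            write_genotypes(table, out_dir / "genotypes.tsv")
            written["genotypes"] = out_dir / "genotypes.tsv"
            pheno.data.to_csv(out_dir / "phenotypes.tsv", sep="\t")
            written["phenotypes"] = out_dir / "phenotypes.tsv"
            truth = pd.concat(
                {"g_md": study.truth["g_md"], "g_pd": study.truth["g_pd"]}, axis=1
            )
            truth.columns = [f"{a}:{b}" for a, b in truth.columns]
            emit("truth_sealed", truth, index=True)
        elif cfg.genotypes and cfg.phenotypes:
            table = read_genotypes(cfg.genotypes)
            pheno = read_phenotypes(cfg.phenotypes)
        else:
            raise ValueError("config needs either simulate: or genotypes:+phenotypes:")
    except Exception as exc:
        raise RuntimeError(f"stage 'input' failed: {exc}") from exc

    try:
        table, report = apply_qc(table, QcThresholds(**cfg.qc))
        emit("qc_report", report.table, index=True)
    except Exception as exc:
        raise RuntimeError(f"stage 'qc' failed: {exc}") from exc

    try:
        matrix, counts = build_dosage_matrix(table, mode=cfg.mode)
        emit("dosage", matrix)
    except Exception as exc:
        raise RuntimeError(f"stage 'dosage' failed: {exc}") from exc

    try:
        scan = poe_scan(table, pheno, cfg.traits, mode=cfg.mode,
                        covariates=cfg.covariates,
                        use_weights=cfg.weight_column is not None)
        emit("scan", scan)
    except Exception as exc:
        raise RuntimeError(f"stage 'scan' failed: {exc}") from exc

    if cfg.permute is not None:
        try:
            perm_rows = []
            maf = estimate_maf(table)
            pairs = table.pairs()
            z_all = assemble_design(pheno, cfg.covariates)
            for trait in cfg.traits:
                y_all, _ = prepare_phenotypes(pheno, trait)
                for snp in table.snp_ids:
                    mot = table.calls.loc[pairs["mother_id"], snp].to_numpy()
                    off = table.calls.loc[pairs.index, snp].to_numpy()
                    ok = (
                        y_all.reindex(pairs.index).notna().to_numpy()
                        & ~np.isnan(mot) & ~np.isnan(off)
                    )
                    res = permute_poe(
                        mot[ok], off[ok],
                        y_all.reindex(pairs.index)[ok].to_numpy(),
                        float(maf[snp]),
                        z=z_all.reindex(pairs.index)[ok].to_numpy() if len(z_all.columns) else None,
                        n_perm=int(cfg.permute.get("n_perm", 999)),
                        seed=int(cfg.permute.get("seed", cfg.seed)),
                    )
                    perm_rows.append(dict(
                        snp_id=snp, trait=trait, observed_z=res.observed_z,
                        p_empirical=res.p_value, n_perm=res.n_permutations,
                        seed=res.seed,
                    ))
            emit("permute", pd.DataFrame(perm_rows))
        except Exception as exc:
            raise RuntimeError(f"stage 'permute' failed: {exc}") from exc

    if cfg.meta_input is not None:
        try:
            summaries = pd.read_csv(cfg.meta_input)
            emit("meta", run_meta(summaries, method={"both": "both", "stouffer": "stouffer",
                                                     "ivw": "ivw"}[cfg.meta_method]))
        except Exception as exc:
            raise RuntimeError(f"stage 'meta' failed: {exc}") from exc

    return written
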