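import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from poefam.families import (
    Dialect,
    GenotypeParseError,
    GenotypeTable,
    PhenotypeTable,
    QcThresholds,
    UndefinedMafError,
    apply_qc,
    coded_allele_frequency,
    estimate_maf,
    genotype_counts,
    hwe_test,
    mendel_inconsistency,
    orient_minor_alleles,
    prepare_phenotypes,
    read_genotypes,
    write_genotypes,
)

from conftest import make_table


# ---------------------------------------------------------------- reading


def _write(tmp_path, text, name="geno.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadGenotypes:
    def test_allele_codes_recode_to_counts(self, tmp_path):
        path = _write(
            tmp_path,
            "subject_id\trole\tmother_id\tsnp1\n"
            "M1\tmother\t\tAA\nM2\tmother\t\tAG\nO1\toffspring\tM1\tGG\n",
        )
        t = read_genotypes(path, Dialect(fmt="alleles"))
        # G is rarer (3 of 6 vs ... A:3, G:3 tie -> alphabetical: A minor)
        assert set(t.calls["snp1"]) <= {0.0, 1.0, 2.0}

    def test_counts_dialect_and_missing_passthrough(self, tmp_path):
        path = _write(
            tmp_path,
            "subject_id\trole\tmother_id\tsnp1\tsnp2\n"
            "M1\tmother\t\t0\t2\nM2\tmother\t\tNN\t1\nO1\toffspring\tM1\t1\t0\n",
        )
        t = read_genotypes(path)
        assert np.isnan(t.calls.loc["M2", "snp1"])
        assert t.calls.loc["O1", "snp1"] == 1.0
        assert t.calls.loc["M1", "snp2"] == 2.0

    def test_majority_coded_allele_is_reoriented(self, tmp_path):
        # coded allele at frequency 0.7 among these subjects: flipping must
        # recode k -> 2-k (brute-force tally check)
        path = _write(
            tmp_path,
            "subject_id\trole\tmother_id\tsnp1\n"
            "M1\tmother\t\tGG\nM2\tmother\t\tGG\nM3\tmother\t\tGA\n"
            "M4\tmother\t\tGA\nM5\tmother\t\tAA\n",
        )
        t = read_genotypes(path, Dialect(fmt="alleles"))
        # raw tallies: G appears 6/10, A 4/10 -> A is minor, counts = #A
        expected = [0.0, 0.0, 1.0, 1.0, 2.0]
        assert list(t.calls["snp1"]) == expected
        assert t.snps.loc["snp1", "minor_allele"] == "A"

    def test_duplicate_subject_id_raises(self, tmp_path):
        path = _write(
            tmp_path,
            "subject_id\trole\tmother_id\tsnp1\nM1\tmother\t\t0\nM1\tmother\t\t1\n",
        )
        with pytest.raises(GenotypeParseError, match="duplicate subject id"):
            read_genotypes(path)

    def test_malformed_code_names_line(self, tmp_path):
        path = _write(
            tmp_path,
            "subject_id\trole\tmother_id\tsnp1\nM1\tmother\t\tzzz\n",
        )
        with pytest.raises(GenotypeParseError, match="line 2"):
            read_genotypes(path)

    def test_ped_reader_roles_and_missing(self, tmp_path):
        ped = _write(
            tmp_path,
            "F1 M1 0 0 2 -9 A A\n"
            "F1 O1 0 M1 1 -9 A G\n"
            "F2 M2 0 0 2 -9 G G\n"
            "F2 O2 0 M2 2 -9 0 0\n",
            name="fam.ped",
        )
        _write(tmp_path, "1 snp1 0 12345\n", name="fam.map")
        t = read_genotypes(ped, Dialect(fmt="ped"))
        assert t.subjects.loc["M1", "role"] == "mother"
        assert t.subjects.loc["O1", "mother_id"] == "M1"
        assert np.isnan(t.calls.loc["O2", "snp1"])
        # G is the rarer allele (3 vs 3 -> tie broken alphabetically: G)
        assert t.calls.loc["O1", "snp1"] == 1.0

    def test_roundtrip_write_read_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 3, size=20).astype(float)
        counts[3] = np.nan
        t = make_table({"snpA": counts[:10]}, {"snpA": counts[10:]})
        write_genotypes(t, tmp_path / "out.tsv")
        back = read_genotypes(tmp_path / "out.tsv")
        assert np.allclose(
            t.calls.to_numpy(), back.calls.to_numpy(), equal_nan=True
        )
        assert list(back.subjects["role"]) == list(t.subjects["role"])


# ---------------------------------------------------------------- MAF


class TestMaf:
    def test_known_tally(self):
        m = [0] * 64 + [1] * 32 + [2] * 4
        t = make_table({"s": m}, {"s": [0] * 100})
        assert estimate_maf(t)["s"] == pytest.approx(0.2)

    def test_monomorphic_major(self):
        t = make_table({"s": [0, 0, 0]}, {"s": [0, 0, 0]})
        assert estimate_maf(t)["s"] == 0.0

    def test_reorientation_of_fixed_minor(self):
        # a single subject homozygous for the coded allele: raw freq 1.0,
        # re-oriented MAF is 0 with flipped coding
        t = make_table({"s": [2]}, {"s": [2]})
        assert coded_allele_frequency(t)["s"] == 1.0
        assert estimate_maf(t)["s"] == 0.0
        flipped_table, flipped = orient_minor_alleles(t)
        assert bool(flipped["s"])
        assert flipped_table.calls.loc["M0", "s"] == 0.0

    def test_all_missing_raises(self):
        t = make_table({"s": [np.nan, np.nan]}, {"s": [0, 1]})
        with pytest.raises(UndefinedMafError):
            estimate_maf(t, roles=("mother",))

    @given(st.lists(st.integers(0, 2), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_flip_symmetry_and_bound(self, counts):
        t = make_table({"s": counts}, {"s": [0] * len(counts)})
        f = coded_allele_frequency(t)["s"]
        t_flipped = make_table({"s": [2 - c for c in counts]}, {"s": [0] * len(counts)})
        assert coded_allele_frequency(t_flipped)["s"] == pytest.approx(1.0 - f)
        assert estimate_maf(t)["s"] <= 0.5


# ---------------------------------------------------------------- HWE


class TestHwe:
    @pytest.mark.parametrize(
        "counts,chi2",
        [((64, 32, 4), 0.0), ((25, 50, 25), 0.0)],
    )
    def test_exact_proportions_give_zero(self, counts, chi2):
        stat, p = hwe_test(counts)
        assert stat == pytest.approx(chi2, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_total_departure(self):
        stat, p = hwe_test((50, 0, 50))
        assert stat == pytest.approx(100.0)
        assert p < 1e-20

    def test_monomorphic_is_not_an_error(self):
        assert hwe_test((10, 0, 0)) == (0.0, 1.0)

    @given(
        st.tuples(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)).filter(
            lambda c: sum(c) > 0
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, counts):
        n = sum(counts)
        q = (counts[1] + 2 * counts[2]) / (2 * n)
        stat, p = hwe_test(counts)
        if q in (0.0, 1.0):
            assert (stat, p) == (0.0, 1.0)
            return
        exp = [n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q**2]
        oracle = sum((o - e) ** 2 / e for o, e in zip(counts, exp))
        assert stat == pytest.approx(oracle, rel=1e-12)
        assert p == pytest.approx(float(stats.chi2.sf(oracle, 1)), rel=1e-12)


# ---------------------------------------------------------------- Mendel


class TestMendel:
    def test_only_opposite_homozygotes_are_inconsistent(self):
        t = make_table(
            {"s": [0, 2, 1, 1, 1]},
            {"s": [2, 0, 0, 1, 2]},
        )
        # first two pairs impossible, heterozygous mother always consistent
        assert mendel_inconsistency(t)["s"] == pytest.approx(2 / 5)

    def test_missing_calls_leave_denominator(self):
        t = make_table({"s": [0, np.nan]}, {"s": [2, 1]})
        assert mendel_inconsistency(t)["s"] == pytest.approx(1.0)

    def test_rate_boundary_half_percent_retained(self):
        mothers = [0] * 200
        offspring = [2] + [0] * 199  # 1/200 = 0.005, exactly at the limit
        t = make_table({"s": mothers}, {"s": offspring})
        rate = mendel_inconsistency(t)["s"]
        assert rate == pytest.approx(0.005)
        kept, report = apply_qc(t, QcThresholds(min_call_rate=0.0, hwe_alpha=0.0))
        assert "s" in kept.snp_ids  # strict inequality: exactly 0.5% passes


# ---------------------------------------------------------------- QC


class TestApplyQc:
    def _clean_counts(self, rng, n, maf=0.3):
        return rng.binomial(1, maf, size=(n, 2)).sum(axis=1).astype(float)

    def test_low_call_rate_excluded_with_reason(self):
        rng = np.random.default_rng(1)
        good = self._clean_counts(rng, 50)
        bad = good.copy()
        bad[:10] = np.nan  # call rate 0.90 over 100 subjects -> 0.95 needed
        t = make_table(
            {"good": good, "bad": bad},
            {"good": self._clean_counts(rng, 50), "bad": self._clean_counts(rng, 50)},
        )
        kept, report = apply_qc(t, QcThresholds(max_mendel_rate=1.0))
        assert kept.snp_ids == ["good"]
        assert "call_rate" in report.table.loc["bad", "reasons"]

    def test_hwe_exactly_at_threshold_is_retained(self, monkeypatch):
        rng = np.random.default_rng(2)
        t = make_table({"s": self._clean_counts(rng, 80)}, {"s": self._clean_counts(rng, 80)})
        _, report = apply_qc(t)
        p = float(report.table.loc["s", "hwe_p"])
        # re-run with the threshold set exactly to this SNP's p-value:
        # exclusion requires a strictly smaller p
        kept, _ = apply_qc(
            t, QcThresholds(hwe_alpha=p, hwe_bonferroni=False, max_mendel_rate=1.0)
        )
        assert "s" in kept.snp_ids

    def test_null_simulation_exclusion_rate(self):
        # clean HWE data at default thresholds: exclusions happen at about
        # the Bonferroni-corrected alpha, i.e. hardly ever
        rng = np.random.default_rng(3)
        n_snps = 40
        t = make_table(
            {f"s{j}": self._clean_counts(rng, 150) for j in range(n_snps)},
            {f"s{j}": self._clean_counts(rng, 150) for j in range(n_snps)},
        )
        # offspring here are independent draws, not transmissions; disable
        # the Mendel filter which would see impossible pairs
        kept, report = apply_qc(t, QcThresholds(max_mendel_rate=1.0))
        assert len(kept.snp_ids) >= n_snps - 2

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        mothers = {f"s{j}": self._clean_counts(rng, 60) for j in range(10)}
        offs = {f"s{j}": self._clean_counts(rng, 60) for j in range(10)}
        mothers["s0"][:10] = np.nan
        t = make_table(mothers, offs)
        once, rep1 = apply_qc(t, QcThresholds(max_mendel_rate=1.0))
        twice, rep2 = apply_qc(once, QcThresholds(max_mendel_rate=1.0))
        assert once.snp_ids == twice.snp_ids

    def test_empty_result_warns(self):
        t = make_table({"s": [0.0, np.nan]}, {"s": [np.nan, np.nan]})
        with pytest.warns(UserWarning, match="failed QC"):
            kept, _ = apply_qc(t)
        assert kept.snp_ids == []


# ---------------------------------------------------------------- traits


def _pheno(**cols):
    n = len(next(iter(cols.values())))
    return PhenotypeTable(
        pd.DataFrame(cols, index=pd.Index([f"O{i}" for i in range(n)], name="subject_id"))
    )


class TestPreparePhenotypes:
    def test_wc_repeats_averaged(self):
        vals, log = prepare_phenotypes(_pheno(wc_1=[80.0], wc_2=[82.0]), "wc")
        assert vals.iloc[0] == pytest.approx(81.0)
        assert log.empty

    def test_insulin_mean_then_log(self):
        vals, _ = prepare_phenotypes(_pheno(insulin_1=[8.0], insulin_2=[10.0]), "insulin")
        assert vals.iloc[0] == pytest.approx(np.log(9.0))

    def test_medication_exclusion_is_trait_specific(self):
        p = _pheno(glucose=[90.0, 95.0], bmi=[24.0, 30.0], diabetes_med=[1, 0])
        glu, log_glu = prepare_phenotypes(p, "glucose")
        bmi, log_bmi = prepare_phenotypes(p, "bmi")
        assert list(glu.index) == ["O1"]
        assert log_glu.iloc[0]["reason"] == "medication:diabetes_med"
        assert len(bmi) == 2 and log_bmi.empty

    def test_nonpositive_log_value_excluded_with_reason(self):
        vals, log = prepare_phenotypes(_pheno(tg=[0.0, 1.5]), "tg")
        assert list(vals.index) == ["O1"]
        assert "nonpositive" in log.iloc[0]["reason"]

    def test_unknown_trait_raises(self):
        with pytest.raises(KeyError):
            prepare_phenotypes(_pheno(bmi=[25.0]), "height")

    def test_sampling_probability_validated(self):
        with pytest.raises(ValueError, match="sampling prob"):
            _pheno(bmi=[25.0], sampling_prob=[0.0])
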