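import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poefam._wls import RankDeficientDesignError, wls_fit
from poefam.regression import (
    AdditiveRegression,
    ParentOfOriginRegression,
    adjust_for_bmi,
    build_ancestry_covariates,
    discovery_screen,
    fit_additive,
    fit_poe,
)


def _random_poe_data(seed, n=300, beta_md=1.0, beta_pd=0.0, noise=2.0):
    rng = np.random.default_rng(seed)
    g_md = rng.binomial(1, 0.2, n).astype(float)
    g_pd = rng.binomial(1, 0.2, n).astype(float)
    z = rng.normal(size=(n, 2))
    w = rng.uniform(0.5, 3.0, n)
    y = 1.0 + beta_md * g_md + beta_pd * g_pd + z @ [0.5, -0.3] + rng.normal(0, noise, n)
    return y, g_md, g_pd, z, w


# ---------------------------------------------------------------- WLS core


class TestWlsCore:
    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_matches_explicit_normal_equations_oracle(self, seed):
        # independent oracle: beta = (X'WX)^-1 X'W y and the pweight
        # sandwich assembled term by term
        rng = np.random.default_rng(seed)
        n = rng.integers(8, 50)
        k = rng.integers(2, min(5, n - 1))
        X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
        y = rng.normal(size=n)
        w = rng.uniform(0.2, 4.0, n)
        fit = wls_fit(y, X, w)

        W = np.diag(w)
        bread = np.linalg.inv(X.T @ W @ X)
        beta = bread @ X.T @ W @ y
        e = y - X @ beta
        meat = X.T @ np.diag((w * e) ** 2) @ X
        cov = bread @ meat @ bread * n / (n - k)
        assert np.allclose(fit.params, beta, atol=1e-10)
        assert np.allclose(fit.cov_robust, cov, atol=1e-10)

    def test_matches_statsmodels_hc1(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        n = 120
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        y = X @ [1, 2, -1, 0.5] + rng.normal(size=n) * 1.7
        w = rng.uniform(0.5, 3.0, n)
        fit = wls_fit(y, X, w)
        ref = sm.WLS(y, X, weights=w).fit(cov_type="HC1")
        assert np.allclose(fit.params, ref.params, atol=1e-10)
        assert np.allclose(fit.se(), ref.bse, atol=1e-10)

    def test_unit_weights_reduce_to_ols_robust(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        n = 90
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ [0.5, 1.0, -2.0] + rng.normal(size=n)
        fit = wls_fit(y, X, None)
        ref = sm.OLS(y, X).fit(cov_type="HC1")
        assert np.allclose(fit.params, ref.params, atol=1e-12)
        assert np.allclose(fit.se(), ref.bse, atol=1e-12)

    def test_rank_deficiency_names_columns(self):
        n = 30
        x = np.random.default_rng(0).normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(RankDeficientDesignError) as err:
            wls_fit(np.zeros(n), X, names=["intercept", "a", "a_twice"])
        assert set(err.value.columns) & {"a", "a_twice"}


# ---------------------------------------------------------------- model fits


class TestAdditive:
    def test_noise_free_recovery_is_exact(self):
        rng = np.random.default_rng(1)
        g_o = rng.integers(0, 3, 40).astype(float)
        y = 2.0 + 0.7 * g_o
        w = rng.uniform(0.5, 2.0, 40)
        res = fit_additive(y, g_o, weights=w)
        assert res.beta_g == pytest.approx(0.7, abs=1e-12)
        assert res.intercept == pytest.approx(2.0, abs=1e-12)

    def test_estimator_api(self):
        y, g_md, g_pd, z, w = _random_poe_data(2)
        est = AdditiveRegression().fit(
            np.column_stack([g_md + g_pd, z]), y, sample_weight=w
        )
        assert est.n_obs_ == len(y)
        assert est.se_ > 0 and 0 <= est.p_value_ <= 1
        pred = est.predict(np.column_stack([g_md + g_pd, z]))
        assert pred.shape == y.shape


class TestPoe:
    def test_noise_free_maternal_effect_exact(self):
        rng = np.random.default_rng(3)
        g_md = rng.binomial(1, 0.3, 60).astype(float)
        g_pd = rng.binomial(1, 0.3, 60).astype(float)
        y = 1.0 + 1.5 * g_md
        res = fit_poe(y, g_md, g_pd)
        assert res.beta_md == pytest.approx(1.5, abs=1e-10)
        assert res.beta_pd == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_constrained_fit_reproduces_additive_model(self, seed):
        # algebraic identity g_md + g_pd = g_o makes the equality-constrained
        # parental-origin model the additive model
        y, g_md, g_pd, z, w = _random_poe_data(seed)
        con = fit_poe(y, g_md, g_pd, z=z, weights=w, constrained=True)
        add = fit_additive(y, g_md + g_pd, z=z, weights=w)
        assert con.beta_md == pytest.approx(add.beta_g, abs=1e-10)
        assert con.se_md == pytest.approx(add.se, abs=1e-10)
        assert np.allclose(con.fit.cov_robust, add.fit.cov_robust, atol=1e-10)

    def test_equality_contrast_in_both_covariances(self):
        y, g_md, g_pd, z, w = _random_poe_data(4, beta_md=2.0, noise=1.0)
        res = fit_poe(y, g_md, g_pd, z=z, weights=w)
        assert 0 <= res.f_p <= 1 and 0 <= res.f_p_classical <= 1
        assert res.f_p < 0.05  # strong true contrast

    def test_collinear_dosages_raise(self):
        n = 50
        g = np.random.default_rng(5).binomial(1, 0.4, n).astype(float)
        with pytest.raises(RankDeficientDesignError):
            fit_poe(np.random.default_rng(6).normal(size=n), g, g)

    def test_constant_covariate_dropped_with_unchanged_estimates(self):
        y, g_md, g_pd, z, w = _random_poe_data(7)
        base = fit_poe(y, g_md, g_pd, z=z, weights=w)
        z_const = np.column_stack([z, np.full(len(y), 3.0)])
        with pytest.warns(UserWarning, match="constant covariate"):
            aug = fit_poe(y, g_md, g_pd, z=z_const, weights=w)
        assert aug.beta_md == pytest.approx(base.beta_md, abs=1e-12)
        assert aug.se_md == pytest.approx(base.se_md, abs=1e-12)


class TestAncestryCovariates:
    def test_reference_only_gives_all_zero(self):
        out = build_ancestry_covariates(["ashkenazi"] * 4)
        assert (out == 0).all() and len(out) == 8

    def test_two_by_two_split(self):
        out = build_ancestry_covariates(["morocco", "morocco", "iraq", "iraq"])
        assert out["morocco"] == 0.5 and out["iraq"] == 0.5
        assert out.drop(["morocco", "iraq"]).eq(0).all()

    def test_quarter_proportions_sum_with_reference(self):
        out = build_ancestry_covariates(["iran", "iraq", "yemen", "ashkenazi"])
        assert out["iran"] == out["iraq"] == out["yemen"] == 0.25
        assert out.sum() == pytest.approx(0.75)  # reference carries the rest

    def test_unknown_stratum_raises(self):
        with pytest.raises(ValueError, match="unknown ancestry stratum"):
            build_ancestry_covariates(["narnia"] * 4)


class TestAdjustForBmi:
    def test_full_mediation_drives_effect_to_null(self):
        rng = np.random.default_rng(9)
        n = 500
        g_md = rng.binomial(1, 0.2, n).astype(float)
        g_pd = rng.binomial(1, 0.2, n).astype(float)
        bmi = 25 + 1.2 * g_md + rng.normal(0, 1.0, n)
        wc = 2.0 * bmi + rng.normal(0, 0.01, n)  # WC acts only through BMI
        unadj, adj = adjust_for_bmi(wc, g_md, g_pd, None, bmi, trait="wc")
        assert unadj.p_md < 0.01
        assert abs(adj.beta_md) < 0.05

    def test_direct_effect_survives_adjustment(self):
        rng = np.random.default_rng(10)
        n = 800
        g_md = rng.binomial(1, 0.3, n).astype(float)
        g_pd = rng.binomial(1, 0.3, n).astype(float)
        bmi = 25 + rng.normal(0, 2.0, n)  # independent of the variant
        wc = 80 + 3.0 * g_md + rng.normal(0, 2.0, n)
        unadj, adj = adjust_for_bmi(wc, g_md, g_pd, None, bmi, trait="wc")
        assert adj.beta_md == pytest.approx(unadj.beta_md, abs=0.3)

    def test_bmi_cannot_adjust_itself(self):
        with pytest.raises(ValueError, match="BMI"):
            adjust_for_bmi(np.zeros(5), np.zeros(5), np.zeros(5), None,
                           np.zeros(5), trait="bmi")


class TestDiscoveryScreen:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["snp_id", "trait", "p_md", "p_pd", "f_p"])

    def test_within_gene_bonferroni_with_any_trait_rule(self):
        # a 10-SNP gene: the waist signal (p_md 0.0027 < 0.005, f_p 0.026)
        # forwards the SNP even though the BMI signal alone (p_md 0.0065)
        # would miss the within-gene cut
        gene_map = {f"rs{i}": "APOB" for i in range(10)}
        res = self._results([
            ("rs0", "wc", 0.0027, 0.6049, 0.0260),
            ("rs0", "bmi", 0.0065, 0.9927, 0.0856),
        ] + [(f"rs{i}", "bmi", 0.5, 0.5, 0.5) for i in range(1, 10)])
        out = discovery_screen(res, gene_map)
        assert bool(out.loc["rs0", "forwarded"])
        assert out.loc["rs0", "traits"] == "wc"
        assert out.loc["rs0", "k_gene"] == 10

    def test_bmi_alone_does_not_forward(self):
        gene_map = {f"rs{i}": "APOB" for i in range(10)}
        res = self._results([("rs0", "bmi", 0.0065, 0.9927, 0.0856)]
                            + [(f"rs{i}", "bmi", 0.5, 0.5, 0.5) for i in range(1, 10)])
        out = discovery_screen(res, gene_map)
        assert not out.loc["rs0", "forwarded"]

    def test_single_snp_gene_nominal_boundary(self):
        out = discovery_screen(
            self._results([("rsX", "bmi", 0.049, 0.9, 0.049)]), {"rsX": "MC4R"}
        )
        assert bool(out.loc["rsX", "forwarded"])

    def test_requires_both_conditions(self):
        out = discovery_screen(
            self._results([("rsX", "bmi", 0.001, 0.9, 0.2)]), {"rsX": "MC4R"}
        )
        assert not out.loc["rsX", "forwarded"]  # f-test not nominal

    def test_uncovered_snp_raises(self):
        with pytest.raises(ValueError, match="gene_map"):
            discovery_screen(self._results([("rsX", "bmi", 0.5, 0.5, 0.5)]), {})
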