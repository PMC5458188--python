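"""Contingency statistics, odds ratios, HWE and the logistic fitter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import ccassoc as ca
from ccassoc import datasets
from ccassoc.association import _assemble_design, hwe_exact_test
from ccassoc.simulate import study_like_config, simulate_cohort


class TestPearsonChi2:
    # published statistics recomputed from the printed counts; gender and
    # rs167007 double as regression fixtures for the no-continuity-
    # correction convention (Yates-corrected gender would be ~0.10)
    @pytest.mark.parametrize(
        "key,expected,df",
        [
            ("smoking", 17.49, 1),
            ("drinking", 15.78, 1),
            ("physical_activity", 16.33, 1),
            ("hbsag", 399.11, 1),
            ("family_history", 39.37, 1),
            ("gender", 0.15, 1),
        ],
    )
    def test_covariate_tables(self, covariate_tables, key, expected, df):
        res = ca.pearson_chi2(covariate_tables[key])
        assert res.df == df
        # printed-precision agreement (the largest statistic is truncated,
        # not rounded, in the source table: 399.1158 printed as 399.11)
        assert abs(res.statistic - expected) < 0.015

    @pytest.mark.parametrize(
        "vid,expected", [("rs73013281", 5.14), ("rs167007", 1.10), ("rs9397984", 1.24)]
    )
    def test_genotype_tables(self, genotype_tables, vid, expected):
        res = ca.pearson_chi2(genotype_tables[vid].counts)
        assert res.df == 2
        assert round(res.statistic, 2) == expected

    def test_proportional_rows_give_zero(self):
        res = ca.pearson_chi2(np.array([[10, 20, 30], [20, 40, 60]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_is_hard_error(self):
        with pytest.raises(ValueError, match="column 1"):
            ca.pearson_chi2(np.array([[5, 0], [3, 0]]))
        with pytest.raises(ValueError, match="row 0"):
            ca.pearson_chi2(np.array([[0, 0], [3, 2]]))

    @given(
        counts=st.lists(st.integers(1, 200), min_size=6, max_size=6),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=40, deadline=None)
    def test_invariant_under_permutation_and_transpose(self, counts, seed):
        arr = np.array(counts, dtype=float).reshape(2, 3)
        rng = np.random.default_rng(seed)
        base = ca.pearson_chi2(arr).statistic
        shuffled = arr[rng.permutation(2)][:, rng.permutation(3)]
        assert ca.pearson_chi2(shuffled).statistic == pytest.approx(base)
        assert ca.pearson_chi2(arr.T).statistic == pytest.approx(base)


class TestCrudeOR:
    def test_heterozygote_contrast(self):
        res = ca.crude_or(ca.TwoByTwo(240, 44, 236, 67))
        assert round(res.or_point, 2) == 1.55
        assert round(res.ci_low, 2) == 1.02
        assert round(res.ci_high, 2) == 2.36

    def test_dominant_contrast(self):
        res = ca.crude_or(ca.TwoByTwo(565, 44, 546, 67))
        assert round(res.or_point, 2) == 1.58
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (1.06, 2.35)

    def test_balanced_table_symmetric_about_one(self):
        res = ca.crude_or(ca.TwoByTwo(10, 10, 10, 10))
        assert res.or_point == pytest.approx(1.0)
        assert res.ci_low * res.ci_high == pytest.approx(1.0)

    def test_zero_cell_haldane_flagged(self):
        res = ca.crude_or(ca.TwoByTwo(5, 0, 3, 4))
        assert res.haldane_corrected
        assert np.isfinite(res.or_point)

    @given(
        a=st.integers(1, 300), b=st.integers(1, 300),
        c=st.integers(1, 300), d=st.integers(1, 300),
    )
    @settings(max_examples=50, deadline=None)
    def test_exposure_swap_inverts_or(self, a, b, c, d):
        t = ca.TwoByTwo(a, b, c, d)
        prod = ca.crude_or(t).or_point * ca.crude_or(t.swapped()).or_point
        assert prod == pytest.approx(1.0, abs=1e-12)

    def test_woolf_ci_coverage_near_nominal(self, rng):
        # 2000 tables at n=600/600 under a known OR: empirical coverage of
        # the generating log-OR within binomial tolerance of 95%
        true_or, p_ctrl, n = 1.7, 0.40, 600
        odds = p_ctrl / (1 - p_ctrl) * true_or
        p_case = odds / (1 + odds)
        log_true = np.log(true_or)
        a = rng.binomial(n, p_case, size=2000)
        c = rng.binomial(n, p_ctrl, size=2000)
        covered = 0
        for ai, ci in zip(a, c):
            res = ca.crude_or(ca.TwoByTwo(int(ai), n - int(ai), int(ci), n - int(ci)))
            covered += res.ci_low <= np.exp(log_true) <= res.ci_high
        assert abs(covered / 2000 - 0.95) <= 0.015


class TestHWE:
    def test_exact_proportions_give_zero(self):
        res = ca.hwe_test((25, 50, 25))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_control_genotypes_goodness_of_fit(self, genotype_tables):
        # hand evaluation: p_alt = 856/1226, expected (55.83, 258.34, 298.83)
        res = ca.hwe_test(genotype_tables["rs73013281"].controls)
        assert res.allele_freq == pytest.approx(856 / 1226)
        assert res.expected_counts.sum() == pytest.approx(613, abs=1e-9)
        assert round(res.statistic, 2) == 4.58
        assert res.df == 1

    def test_monomorphic_sample_flagged(self):
        res = ca.hwe_test((0, 0, 100))
        assert res.statistic == 0.0 and res.monomorphic

    @given(n_het=st.integers(0, 60), n_hom=st.integers(0, 60))
    @settings(max_examples=40, deadline=None)
    def test_statistic_zero_iff_counts_match_expectations(self, n_het, n_hom):
        obs = np.array([25, n_het, n_hom])
        res = ca.hwe_test(obs)
        matches = np.allclose(obs, res.expected_counts, atol=1e-9)
        assert (res.statistic < 1e-18) == matches

    def test_exact_test_agrees_with_asymptotic_in_large_balanced_sample(self):
        p_asym = ca.hwe_test((160, 480, 360)).p_value
        p_exact = hwe_exact_test((160, 480, 360))
        assert 0 <= p_exact <= 1
        assert abs(p_exact - p_asym) < 0.2  # same order, both ~nonsignificant


class TestLogisticFit:
    @pytest.mark.parametrize(
        "t",
        [
            ca.TwoByTwo(240, 44, 236, 67),
            ca.TwoByTwo(565, 44, 546, 67),
            ca.TwoByTwo(522, 89, 520, 90),
            ca.TwoByTwo(536, 75, 530, 81),
        ],
    )
    def test_single_binary_predictor_reproduces_cross_product(self, t):
        y = np.repeat([1, 1, 0, 0], [t.a, t.b, t.c, t.d])
        x = np.repeat([1, 0, 1, 0], [t.a, t.b, t.c, t.d]).astype(float)
        fit = ca.fit_logistic(y, x[:, None], terms=["x"])
        assert fit.converged
        cross = t.a * t.d / (t.b * t.c)
        assert np.exp(fit.coef("x")) == pytest.approx(cross, rel=1e-6)

    def test_independent_predictor_gives_null_coefficient(self):
        y = np.tile([1, 0], 100)
        x = np.tile([1.0, 1.0, 0.0, 0.0], 50)
        fit = ca.fit_logistic(y, x[:, None], terms=["x"])
        assert abs(fit.coef("x")) < 1e-8

    def test_matches_statsmodels_ml_fit(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 200
        x1 = rng.binomial(1, 0.4, n).astype(float)
        x2 = rng.normal(size=n)
        eta = -0.5 + 0.8 * x1 + 0.3 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        X = np.column_stack([x1, x2])
        fit = ca.fit_logistic(y, X, terms=["x1", "x2"])
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        assert fit.converged
        np.testing.assert_allclose(fit.beta, ref.params, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(fit.loglik, ref.llf, rtol=1e-8)
        np.testing.assert_allclose(
            fit.se(), ref.bse, rtol=1e-5, atol=1e-8
        )

    def test_separation_flagged_not_silently_converged(self):
        y = np.repeat([1, 0], 20)
        x = y.astype(float)  # perfect separation
        fit = ca.fit_logistic(y, x[:, None], terms=["x"])
        assert not fit.converged

    def test_constant_column_rejected(self):
        y = np.tile([1, 0], 10)
        with pytest.raises(ValueError, match="constant"):
            ca.fit_logistic(y, np.ones((20, 1)), terms=["x"])


class TestAdjustedOR:
    def test_no_covariates_equals_crude(self, table_cohort, variants):
        var = variants["rs9397984"]
        res = ca.adjusted_or(table_cohort, var, ca.GeneticModelCoding("recessive"))[0]
        tab = datasets.genotype_tables()["rs9397984"]
        crude = ca.crude_or(ca.collapse(tab, "recessive", var))
        assert res.or_point == pytest.approx(crude.or_point, rel=1e-6)
        assert not res.adjusted

    def test_codominant_reproduces_published_crude_ors(self, table_cohort, variants):
        res = ca.adjusted_or(
            table_cohort, variants["rs73013281"], ca.GeneticModelCoding("codominant")
        )
        assert [round(r.or_point, 2) for r in res] == [1.55, 1.60]
        assert res[0].contrast_label == "CT vs CC"

    def test_recovers_generating_or_with_confounders(self):
        # 95% Wald CIs should cover the generating OR at ~nominal rate
        covered = 0
        for seed in range(20):
            cfg = study_like_config(seed=seed)
            cfg.genetic_effects = {"rs73013281": ("dominant", float(np.log(1.7)))}
            cfg.covariate_effects = {"smoking": 0.6, "hbsag": 2.0}
            cohort = simulate_cohort(cfg)
            res = ca.adjusted_or(
                cohort,
                cohort.variant("rs73013281"),
                ca.GeneticModelCoding("dominant"),
                covariates=("smoking", "hbsag", "age"),
            )[0]
            assert res.adjusted and res.covariates == ("smoking", "hbsag", "age")
            covered += res.ci_low <= 1.7 <= res.ci_high
        assert covered >= 16


class TestGeneticModelSelection:
    def test_dominant_truth_ranked_first(self):
        cfg = study_like_config(seed=99)
        cfg.n_cases = cfg.n_controls = 2000
        cfg.variants = cfg.variants[:1]
        cfg.variants[0] = type(cfg.variants[0])(cfg.variants[0].variant, 0.30)
        cfg.genetic_effects = {"rs73013281": ("dominant", float(np.log(2.5)))}
        cohort = simulate_cohort(cfg)
        fits = ca.select_genetic_model(cohort, cohort.variant("rs73013281"))
        assert fits[0].coding.name == "dominant"
        assert len(fits) == 4  # nothing silently discarded

    def test_reports_published_dominant_contrast(self, table_cohort, variants):
        fits = ca.select_genetic_model(table_cohort, variants["rs73013281"])
        by_name = {f.coding.name: f for f in fits}
        dom = by_name["dominant"].or_results[0]
        assert round(dom.or_point, 2) == 1.58

    def test_null_data_nonsignificant_in_expectation(self):
        cfg = study_like_config(seed=7)
        cohort = simulate_cohort(cfg)
        fits = ca.select_genetic_model(cohort, cohort.variant("rs167007"))
        assert len(fits) == 4
        # ranking exists; a null variant should rarely show p < 0.05
        assert min(r.p_value for f in fits for r in f.or_results) > 0.01


def test_design_assembly_complete_case(table_cohort, variants):
    y, X, terms, gterms, labels = _assemble_design(
        table_cohort, variants["rs73013281"], ca.GeneticModelCoding("dominant"), ()
    )
    # 611+614 minus the 3 subjects without a call at this variant
    assert y.size == 609 + 613
    assert gterms[0].startswith("rs73013281")
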