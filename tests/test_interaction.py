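"""Stratified ORs, multiplicative product-term test, RERI and the
stratified bootstrap additive-interaction test."""

import numpy as np
import pytest

import ccassoc as ca
from ccassoc import datasets
from ccassoc.association import LogisticFit
from ccassoc.cohort import CohortTable, VariantDef
from ccassoc.interaction import (
    JOINT_TERMS,
    additive_interaction_bootstrap,
    joint_exposure_design,
    multiplicative_interaction,
    pairwise_interaction,
    reri,
    stratified_ors,
)
from ccassoc.simulate import InteractionSpec, study_like_config, simulate_cohort

DOM = ca.GeneticModelCoding("dominant")


def fit_with_ors(or10, or01, or11):
    """Minimal converged joint-exposure fit with prescribed cell ORs."""
    beta = np.log([0.1, or10, or01, or11])
    return LogisticFit(
        terms=("intercept", *JOINT_TERMS),
        beta=beta,
        vcov=np.eye(4),
        loglik=0.0,
        converged=True,
        n_used=100,
    )


class TestJointDesign:
    def test_exactly_one_indicator_per_nonreference_subject(self, rng):
        g = rng.integers(0, 2, 500)
        e = rng.integers(0, 2, 500)
        cols, terms = joint_exposure_design(g, e)
        assert terms == list(JOINT_TERMS)
        row_sums = cols.sum(axis=1)
        ref = (g == 0) & (e == 0)
        assert (row_sums[ref] == 0).all()
        assert (row_sums[~ref] == 1).all()


class TestRERI:
    def test_exact_additivity_gives_zero(self):
        assert reri(fit_with_ors(1.5, 1.5, 2.0)) == pytest.approx(0.0)

    def test_multiplicativity_of_joint_risks_implies_superadditivity(self):
        # OR11 = OR10 * OR01 with both > 1 forces RERI > 0
        for o1, o2 in [(1.5, 1.5), (2.0, 1.2), (3.0, 1.01)]:
            assert reri(fit_with_ors(o1, o2, o1 * o2)) > 0

    def test_published_activity_cells_reproduce_derived_value(self, activity_cohort):
        # independent closed form from the printed counts, reference
        # (CC, active): OR10=(200*28)/(20*262), OR01=(24*28)/(20*39),
        # OR11=(365*28)/(20*284)
        or10 = (200 * 28) / (20 * 262)
        or01 = (24 * 28) / (20 * 39)
        or11 = (365 * 28) / (20 * 284)
        expected = or11 - or10 - or01 + 1.0
        res = pairwise_interaction(
            activity_cohort,
            activity_cohort.variant("rs73013281"),
            "physical_activity",
            n_boot=200,
            seed=4,
        )
        assert expected == pytest.approx(0.869, abs=0.002)
        assert res.reri_point == pytest.approx(expected, rel=1e-9)

    def test_missing_term_is_hard_error(self):
        fit = fit_with_ors(1.5, 1.5, 2.0)
        with pytest.raises(ValueError, match="missing"):
            reri(fit, terms=("nope", "e_only", "g_and_e"))


class TestStratifiedORs:
    def test_published_activity_strata_crude_ors(self, activity_cohort):
        out = stratified_ors(
            activity_cohort, activity_cohort.variant("rs73013281"), DOM,
            "physical_activity",
        )
        assert out[1].or_point == pytest.approx((365 * 39) / (24 * 284), rel=1e-9)
        assert out[0].or_point == pytest.approx((200 * 28) / (20 * 262), rel=1e-9)
        assert round(out[1].or_point, 2) == 2.09
        assert round(out[0].or_point, 2) == 1.07

    def test_constant_stratifier_equals_unstratified(self, rng):
        var = VariantDef("v", "C", "T")
        y = rng.integers(0, 2, 200)
        g = rng.integers(0, 3, 200)
        cohort = CohortTable(y, [var], {"v": g}, {"s": np.ones(200)})
        out = stratified_ors(cohort, var, DOM, "s")
        assert list(out) == [1]
        tab = ca.genotype_counts(cohort, "v")
        crude = ca.crude_or(ca.collapse(tab, "dominant", var))
        assert out[1].or_point == pytest.approx(crude.or_point)

    def test_zero_cell_stratum_haldane_with_warning(self):
        var = VariantDef("v", "C", "T")
        y = [1] * 10 + [0] * 10
        g = [1] * 5 + [0] * 5 + [0] * 10  # no exposed controls in stratum 1
        s = np.ones(20)
        cov = np.resize([0.0, 1.0], 20)
        cohort = CohortTable(y, [var], {"v": g}, {"s": s, "x": cov})
        with pytest.warns(UserWarning, match="zero cell"):
            out = stratified_ors(cohort, var, DOM, "s", covariates=("x",))
        assert out[1].haldane_corrected


class TestMultiplicativeInteraction:
    def test_saturated_identity_product_term_equals_or_ratio(self, activity_cohort):
        or_int, p, _ = multiplicative_interaction(
            activity_cohort, activity_cohort.variant("rs73013281"), DOM,
            "physical_activity",
        )
        strata = stratified_ors(
            activity_cohort, activity_cohort.variant("rs73013281"), DOM,
            "physical_activity",
        )
        ratio = strata[1].or_point / strata[0].or_point
        assert or_int == pytest.approx(ratio, rel=1e-6)
        assert 0 <= p <= 1

    def test_equal_stratum_ors_give_unit_interaction(self):
        var = VariantDef("v", "C", "T")
        # both strata have cross-product OR exactly 3
        cells = {0: ((20, 30), (40, 20)), 1: ((10, 15), (20, 10))}
        cohort = datasets.cohort_from_joint_counts(var, "e", cells)
        or_int, p, _ = multiplicative_interaction(cohort, var, DOM, "e")
        assert or_int == pytest.approx(1.0, rel=1e-6)
        assert p > 0.9

    def test_detects_strong_interaction_at_study_size(self):
        # stratum ORs like the published 2.75 vs 0.89 should reject far
        # above the 5% level at the study sample size
        rejections = 0
        n_rep = 40
        for s in range(n_rep):
            cfg = study_like_config(seed=0)
            cfg.genetic_effects = {"rs73013281": ("dominant", float(np.log(0.89)))}
            cfg.covariate_effects = {"physical_activity": float(np.log(1.2))}
            cfg.interaction = InteractionSpec(
                "rs73013281", "dominant", "physical_activity",
                "multiplicative", 2.75 / 0.89,
            )
            cfg.seed = 3000 + s
            cohort = simulate_cohort(cfg)
            _, p, _ = multiplicative_interaction(
                cohort, cohort.variant("rs73013281"), DOM, "physical_activity"
            )
            rejections += p < 0.05
        assert rejections / n_rep > 0.5


class TestAdditiveBootstrap:
    def test_seed_reproducibility_bitwise(self, activity_cohort):
        var = activity_cohort.variant("rs73013281")
        r1 = additive_interaction_bootstrap(
            activity_cohort, var, DOM, "physical_activity", n_boot=500, seed=99
        )
        r2 = additive_interaction_bootstrap(
            activity_cohort, var, DOM, "physical_activity", n_boot=500, seed=99
        )
        assert r1[2] == r2[2] and r1[1] == r2[1]
        assert np.array_equal(r1[4], r2[4])

    def test_seed_is_mandatory(self, activity_cohort):
        var = activity_cohort.variant("rs73013281")
        with pytest.raises(ValueError, match="seed"):
            additive_interaction_bootstrap(
                activity_cohort, var, DOM, "physical_activity", n_boot=10
            )

    def test_ci_brackets_point_and_p_in_range(self, activity_cohort):
        var = activity_cohort.variant("rs73013281")
        point, ci, p, n_fail, boot = additive_interaction_bootstrap(
            activity_cohort, var, DOM, "physical_activity", n_boot=2000, seed=1
        )
        assert ci[0] <= point <= ci[1]
        assert 2 / 2000 <= p <= 1
        assert n_fail == 0

    def test_strong_superadditivity_detected(self):
        cfg = study_like_config(seed=0)
        cfg.genetic_effects = {"rs73013281": ("dominant", float(np.log(1.3)))}
        cfg.covariate_effects = {"physical_activity": float(np.log(1.3))}
        cfg.interaction = InteractionSpec(
            "rs73013281", "dominant", "physical_activity", "additive", 2.5
        )
        cfg.seed = 2024
        cohort = simulate_cohort(cfg)
        point, ci, p, _, _ = additive_interaction_bootstrap(
            cohort, cohort.variant("rs73013281"), DOM, "physical_activity",
            n_boot=2000, seed=17,
        )
        assert p < 0.05
        assert ci[0] > 0

    def test_covariate_path_matches_fast_path_point_estimate(self, activity_cohort):
        # the observed RERI is the same whether computed from the crude
        # saturated cells or from a logistic fit with a null covariate
        var = activity_cohort.variant("rs73013281")
        n = activity_cohort.n_subjects
        vals = np.resize([0.0, 1.0], n)
        cohort = CohortTable(
            activity_cohort.phenotype,
            list(activity_cohort.variants.values()),
            {"rs73013281": activity_cohort.calls("rs73013281")},
            {
                "physical_activity": activity_cohort.covariate("physical_activity"),
                "noise": vals,
            },
        )
        crude = additive_interaction_bootstrap(
            cohort, var, DOM, "physical_activity", n_boot=100, seed=5
        )
        adj = additive_interaction_bootstrap(
            cohort, var, DOM, "physical_activity", covariates=("noise",),
            n_boot=100, seed=5,
        )
        assert adj[0] == pytest.approx(crude[0], abs=5e-3)


def test_pairwise_interaction_bundles_everything(activity_cohort):
    res = pairwise_interaction(
        activity_cohort,
        activity_cohort.variant("rs73013281"),
        "physical_activity",
        n_boot=500,
        seed=12,
    )
    assert set(res.stratum_ors) == {0, 1}
    assert res.or_interaction == pytest.approx(
        res.stratum_ors[1].or_point / res.stratum_ors[0].or_point, rel=1e-6
    )
    assert res.reri_ci[0] <= res.reri_point <= res.reri_ci[1]
    assert 0 <= res.p_multiplicative <= 1 and 0 <= res.p_additive <= 1
    assert res.ap == pytest.approx(res.reri_point / ((365 * 28) / (20 * 284)), rel=1e-6)
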