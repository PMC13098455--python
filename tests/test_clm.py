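"""Maxdiff conditional logit: likelihood, fitting, robust SEs, subgroups."""

import math

import numpy as np
import pytest

from sowbws import (
    SubgroupSpec,
    UtilityProfile,
    expand_task,
    fit,
    fit_stats,
    loglik,
    simulate_choices,
    simulate_respondents,
    subgroup_fit,
    subgroup_table,
)
from sowbws.clm import collapse_expansion, significance_stars
from sowbws.cohort import BWResponse

from conftest import POOLED_COEFFICIENTS


class TestExpansion:
    def test_three_attribute_task_gives_six_alternatives(self):
        resp = BWResponse("R1", 0, best="SCLH", worst="STN")
        exp = expand_task(("SCLH", "BCS", "STN"), resp)
        assert len(exp.pairs) == 6
        assert exp.chosen_pair == ("SCLH", "STN")

    def test_round_trip(self):
        resp = BWResponse("R1", 3, best="BCS", worst="SCLH")
        exp = expand_task(("SCLH", "BCS", "STN"), resp)
        assert collapse_expansion(exp) == ("BCS", "SCLH")

    def test_pick_outside_task_is_error(self):
        resp = BWResponse("R1", 0, best="LS", worst="STN")
        with pytest.raises(ValueError, match="not both in task"):
            expand_task(("SCLH", "BCS", "STN"), resp)

    def test_dataset_expands_to_357_observations(self, cohort_51):
        task_attrs = {t.task_id: t.attributes for t in cohort_51.design}
        expanded = [
            expand_task(task_attrs[r.task_id], r) for r in cohort_51.responses
        ]
        assert len(expanded) == 357
        assert all(len(e.pairs) == 6 for e in expanded)


class TestLoglik:
    def test_null_loglik_is_minus_T_log6(self, cohort_51):
        ll = loglik(np.zeros(6), cohort_51, reference="P")
        assert ll == pytest.approx(-357 * math.log(6), abs=1e-10)
        assert round(ll, 1) == -639.7

    def test_single_task_hand_enumeration(self, bound_tasks):
        from sowbws.cohort import Respondent, SurveyDataset

        person = Respondent("R1", "female", "18-40", "<=10yr", "college", "<=5000")
        task = bound_tasks[0]  # (SCLH, BCS, STN)
        ds = SurveyDataset(
            roster=[person],
            design=[task],
            responses=[BWResponse("R1", task.task_id, "SCLH", "STN")],
        )
        u = {"SCLH": 0.7, "BCS": -0.2, "STN": 0.0}
        order = [c for c in ds.attribute_codes if c != "STN"]
        denom = sum(
            math.exp(u[b] - u[w])
            for b in task.attributes for w in task.attributes if b != w
        )
        expected = math.log(math.exp(u["SCLH"] - u["STN"]) / denom)
        ll = loglik([u[c] for c in order], ds, reference="STN")
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_task_permutation(self, cohort_51):
        import copy

        beta = np.linspace(-0.5, 1.5, 6)
        ll = loglik(beta, cohort_51, reference="P")
        shuffled = copy.copy(cohort_51)
        rng = np.random.default_rng(0)
        shuffled.responses = [
            cohort_51.responses[i]
            for i in rng.permutation(len(cohort_51.responses))
        ]
        assert loglik(beta, shuffled, reference="P") == pytest.approx(ll, abs=1e-9)

    def test_analytic_gradient_matches_finite_differences(self, cohort_51, rng):
        h = 1e-6
        for _ in range(20):
            beta = rng.normal(scale=1.0, size=6)
            _, grad = loglik(beta, cohort_51, reference="P", return_grad=True)
            for j in range(6):
                e = np.zeros(6)
                e[j] = h
                num = (
                    loglik(beta + e, cohort_51, reference="P")
                    - loglik(beta - e, cohort_51, reference="P")
                ) / (2 * h)
                assert abs(num - grad[j]) / max(1.0, abs(grad[j])) < 1e-6


class TestFitStats:
    def test_reproduces_published_fit_statistics(self):
        stats = fit_stats(-544.2, n_tasks=357, k=3, K=6)
        assert round(stats.ll_null, 1) == -639.7
        assert round(stats.pseudo_r2, 4) == 0.1492
        assert round(stats.aic) == 1100
        assert round(stats.bic) == 1124

    def test_null_model_zero_pseudo_r2(self):
        ll0 = -357 * math.log(6)
        assert fit_stats(ll0, 357, 3, 6).pseudo_r2 == pytest.approx(0.0, abs=1e-12)

    def test_definitional_identities(self, cohort_51):
        clm = fit(cohort_51, reference="P")
        assert clm.aic == pytest.approx(-2 * clm.ll_model + 12, abs=1e-9)
        assert clm.bic == pytest.approx(
            -2 * clm.ll_model + 6 * math.log(357), abs=1e-9
        )
        assert clm.ll_model >= clm.ll_null
        assert 0 <= clm.pseudo_r2 < 1
        assert clm.n_obs == 357 and clm.K == 6


class TestFit:
    def test_parameter_recovery_at_500_respondents(self, bound_tasks, pooled_profile):
        roster = simulate_respondents(500, seed=42)
        ds = simulate_choices(roster, bound_tasks, pooled_profile, seed=42)
        clm = fit(ds, reference="P")
        truth = np.array([POOLED_COEFFICIENTS[c] for c in clm.codes])
        assert clm.converged
        assert np.all(np.abs(clm.beta - truth) <= 0.15)

    def test_null_data_small_coefficients(self, bound_tasks):
        null = UtilityProfile({c: 0.0 for c in POOLED_COEFFICIENTS})
        roster = simulate_respondents(400, seed=8, mode="multinomial")
        ds = simulate_choices(roster, bound_tasks, null, seed=8)
        clm = fit(ds, reference="P")
        assert np.all(np.abs(clm.beta) < 0.2)
        assert clm.pseudo_r2 < 0.01

    def test_default_reference_is_lowest_bw_attribute(self, cohort_51):
        clm = fit(cohort_51)
        from sowbws import tally

        B, W, _ = tally(cohort_51)
        assert clm.reference == (B - W).idxmin()

    def test_reference_shift_relation(self, cohort_51):
        """Refitting against another reference shifts all utilities by the
        new reference's old coefficient."""
        clm_p = fit(cohort_51, reference="P")
        clm_ls = fit(cohort_51, reference="LS")
        util_p = dict(zip(clm_p.codes, clm_p.beta), P=0.0)
        util_ls = dict(zip(clm_ls.codes, clm_ls.beta), LS=0.0)
        shift = util_p["LS"]
        for code, value in util_p.items():
            assert util_ls[code] == pytest.approx(value - shift, abs=5e-4)
        assert clm_p.ll_model == pytest.approx(clm_ls.ll_model, abs=1e-6)

    def test_robust_close_to_classical_on_independent_tasks(self, bound_tasks, pooled_profile):
        # with one task per respondent, clusters are single observations
        roster = simulate_respondents(3000, seed=13, mode="multinomial")
        design = bound_tasks[:1]
        ds = simulate_choices(roster, design, pooled_profile, seed=13)
        clm = fit(ds, reference="STN")  # reference must appear in the task
        ratio = clm.robust_se / clm.classical_se
        assert np.all((ratio > 0.8) & (ratio < 1.25))

    def test_separation_flagged_not_silent(self, bound_tasks):
        profile = UtilityProfile(
            {"SCLH": 50.0, "BCS": 0.0, "SCLS": 0.0, "STN": 0.0,
             "LS": 0.0, "SB": 0.0, "P": 0.0}
        )
        roster = simulate_respondents(30, seed=2)
        ds = simulate_choices(roster, bound_tasks, profile, seed=2)
        from sowbws.clm import DivergenceWarning

        with pytest.warns(DivergenceWarning):
            clm = fit(ds, reference="P")
        assert "SCLH" in clm.diverging

    def test_stars_thresholds(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == "NS"


class TestSubgroups:
    def test_gender_split_sizes(self, cohort_51):
        spec = SubgroupSpec("gender", ("female", "male"))
        fits = subgroup_fit(cohort_51, spec, reference="P")
        assert fits["female"].n_respondents == 18
        assert fits["male"].n_respondents == 33
        assert fits["female"].n_obs == 126
        assert fits["male"].n_obs == 231

    def test_identical_generating_utilities_agree(self, bound_tasks, pooled_profile):
        roster = simulate_respondents(400, seed=21, mode="multinomial")
        ds = simulate_choices(roster, bound_tasks, pooled_profile, seed=21)
        spec = SubgroupSpec("gender", ("female", "male"))
        fits = subgroup_fit(ds, spec, reference="P")
        diff = fits["female"].beta - fits["male"].beta
        joint_se = np.sqrt(
            fits["female"].robust_se ** 2 + fits["male"].robust_se ** 2
        )
        assert np.all(np.abs(diff) < 4 * joint_se)

    def test_category_loglikelihoods_nest_pooled(self, cohort_51):
        pooled = fit(cohort_51, reference="P")
        spec = SubgroupSpec("gender", ("female", "male"))
        fits = subgroup_fit(cohort_51, spec, reference="P")
        assert (
            fits["female"].ll_model + fits["male"].ll_model
            >= pooled.ll_model - 1e-8
        )

    def test_empty_category_is_error(self, cohort_51):
        spec = SubgroupSpec("gender", ("female", "nonbinary-unrecorded"))
        with pytest.raises(ValueError, match="no respondents"):
            subgroup_fit(cohort_51, spec, reference="P")

    def test_long_table_shape(self, cohort_51):
        specs = [
            SubgroupSpec("gender", ("female", "male")),
            SubgroupSpec("age_band", ("18-40", ">40")),
        ]
        table = subgroup_table(cohort_51, specs, reference="P")
        assert len(table) == 4 * 6  # categories x non-reference attributes
        assert set(table["subgroup"]) == {"gender", "age_band"}
        assert {"coefficient", "robust_se", "p", "stars"} <= set(table.columns)
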