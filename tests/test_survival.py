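"""Survival suite: KM against hand product-limit, log-rank O-E arithmetic,
event rates, Cox fits against a brute-force partial-likelihood oracle,
Schoenfeld diagnostic, and outcome models A-C."""

import numpy as np
import pandas as pd
import pytest

from gdmtopt import (
    TruthParams,
    event_rate_per_100py,
    fit_cox,
    generate_score_panel,
    km_estimate,
    logrank_test,
    schoenfeld_ph_test,
)
from gdmtopt.survival import CoxOutcomeModel
from oracles import grid_search_cox, logrank_observed_minus_expected, product_limit


class TestKaplanMeier:
    def test_no_events_keeps_survival_at_one(self):
        curve = km_estimate([5, 6, 7], [False, False, False])["all"]
        assert (curve.survival == 1.0).all()

    def test_two_subject_hand_computation(self):
        curve = km_estimate([1, 2], [True, True])["all"]
        assert curve.survival_at(1) == pytest.approx(0.5)
        assert curve.survival_at(2) == pytest.approx(0.0)

    def test_censoring_shrinks_risk_set(self):
        curve = km_estimate([1, 2, 3], [True, False, True])["all"]
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(3) == pytest.approx(0.0)

    def test_matches_hand_product_limit_on_random_data(self):
        rng = np.random.default_rng(3)
        times = rng.integers(1, 20, 60).astype(float)
        events = rng.random(60) < 0.6
        curve = km_estimate(times, events)["all"]
        for t, s in product_limit(times, events).items():
            assert curve.survival_at(t) == pytest.approx(s)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(4)
        times = rng.integers(1, 30, 80).astype(float)
        curve = km_estimate(times, np.ones(80, dtype=bool))["all"]
        for t in np.unique(times):
            assert curve.survival_at(t) == pytest.approx((times > t).mean())

    def test_monotone_and_banded(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(5, 100)
        events = rng.random(100) < 0.7
        curve = km_estimate(times, events)["all"]
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert (curve.ci_lower <= curve.survival + 1e-12).all()
        assert (curve.ci_upper >= curve.survival - 1e-12).all()


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t, e = [1, 2, 3, 4], [True, True, False, True]
        stat, df, p = logrank_test(t + t, e + e, ["a"] * 4 + ["b"] * 4)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [True, True], ["a", "a"])

    def test_matches_hand_observed_minus_expected(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [True, True, True, True, False, False]
        groups = ["a", "b", "a", "b", "a", "b"]
        stat, _, _ = logrank_test(times, events, groups)
        o_minus_e, var = logrank_observed_minus_expected(times, events, groups)
        assert stat == pytest.approx(o_minus_e**2 / var)

    def test_power_against_strong_separation(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(40):
            t1 = rng.exponential(1.0, 200)
            t2 = rng.exponential(3.0, 200)
            _, _, p = logrank_test(
                np.concatenate([t1, t2]), np.ones(400, bool),
                ["a"] * 200 + ["b"] * 200)
            hits += p < 0.05
        assert hits >= 38  # >= 95% rejection at hazard ratio 3


class TestEventRate:
    def test_printed_cohort_rate(self):
        assert event_rate_per_100py(582, 1496.0) == pytest.approx(38.9, abs=0.05)

    def test_zero_events_is_zero(self):
        assert event_rate_per_100py(0, 10.0) == 0.0

    def test_simple_arithmetic(self):
        assert event_rate_per_100py(10, 25.0) == pytest.approx(40.0)

    def test_zero_person_years_rejected(self):
        with pytest.raises(ValueError):
            event_rate_per_100py(1, 0.0)


SMALL_DATASETS = [
    pd.DataFrame({"t": [1, 2, 3, 4, 5, 6], "e": [1, 1, 0, 1, 0, 1],
                  "x": [1.0, 0, 1, 0, 1, 0]}),
    pd.DataFrame({"t": [1, 1, 2, 3], "e": [1, 1, 1, 0], "x": [1.0, 0, 1, 0]}),
    pd.DataFrame({"t": [2, 2, 2, 5, 7, 9, 9, 11], "e": [1, 0, 1, 1, 0, 1, 1, 0],
                  "x": [0.5, -0.5, 1.0, 0.0, -1.0, 0.5, -0.5, 1.0]}),
    pd.DataFrame({"t": [1, 2, 3], "e": [1, 1, 1], "x": [0.0, 1.0, 0.0]}),
    pd.DataFrame({"t": [4, 4, 6, 6, 8], "e": [1, 1, 1, 1, 1],
                  "x": [1.0, 1.0, 0.0, 1.0, 0.0]}),
]


class TestCoxFits:
    @pytest.mark.parametrize("df", SMALL_DATASETS)
    def test_coefficient_matches_partial_likelihood_grid_search(self, df):
        fit = fit_cox(df, "t", "e", ["x"])
        assert float(fit.coef["x"]) == pytest.approx(grid_search_cox(df), abs=1e-4)

    def test_null_covariate_is_near_zero(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"t": rng.exponential(1, 500),
                           "e": np.ones(500, bool),
                           "x": rng.permutation(rng.normal(size=500))})
        fit = fit_cox(df, "t", "e", ["x"])
        assert abs(float(fit.coef["x"])) < 3 * float(fit.se["x"])

    def test_integer_weights_equal_row_duplication(self):
        # weights > 1 only on censored rows: with Efron tie handling a
        # weighted event row is a single event, not a tie, so exact
        # duplication equivalence requires unit event weights
        df = pd.DataFrame({"t": [1, 2, 3, 4, 5], "e": [1, 1, 0, 1, 1],
                           "x": [1.0, 0, 1, 0, 1], "w": [1.0, 1, 3, 1, 1]})
        weighted = fit_cox(df, "t", "e", ["x"], weights_col="w")
        dup = df.loc[df.index.repeat(df["w"].astype(int))].drop(columns="w")
        duplicated = fit_cox(dup, "t", "e", ["x"])
        assert float(weighted.coef["x"]) == pytest.approx(
            float(duplicated.coef["x"]), abs=1e-10)

    def test_hr_and_ci_consistent_with_coef(self):
        fit = fit_cox(SMALL_DATASETS[0], "t", "e", ["x"])
        assert float(fit.hr["x"]) == pytest.approx(np.exp(float(fit.coef["x"])))
        assert float(fit.ci_lower["x"]) < float(fit.hr["x"]) < float(fit.ci_upper["x"])

    def test_constant_covariate_rejected(self):
        df = SMALL_DATASETS[0].assign(x=1.0)
        with pytest.raises(ValueError, match="constant"):
            fit_cox(df, "t", "e", ["x"])

    def test_no_events_rejected(self):
        df = SMALL_DATASETS[0].assign(e=0)
        with pytest.raises(ValueError, match="event"):
            fit_cox(df, "t", "e", ["x"])

    def test_robust_and_model_se_agree_for_independent_subjects(self):
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.3 * x))
        df = pd.DataFrame({"t": t, "e": np.ones(n, bool), "x": x,
                           "id": np.arange(n)})
        model = fit_cox(df, "t", "e", ["x"])
        robust = fit_cox(df, "t", "e", ["x"], cluster_col="id")
        ratio = float(robust.se["x"]) / float(model.se["x"])
        assert 0.85 < ratio < 1.15


class TestSchoenfeld:
    def test_single_event_rejected(self):
        df = pd.DataFrame({"t": [1.0, 2.0, 3.0], "e": [1, 0, 0],
                           "x": [1.0, 0.0, 1.0]})
        fit = fit_cox(df, "t", "e", ["x"])
        with pytest.raises(ValueError):
            schoenfeld_ph_test(fit)

    def test_proportional_data_passes_and_nonproportional_fails(self):
        rng = np.random.default_rng(9)
        n = 400
        x = rng.normal(size=n)
        # proportional hazards
        ph = pd.DataFrame({"t": rng.exponential(np.exp(-0.5 * x)),
                           "e": np.ones(n, bool), "x": x})
        out_ph = schoenfeld_ph_test(fit_cox(ph, "t", "e", ["x"]))
        # effect reverses over time -> strongly non-proportional
        u = rng.random(n)
        t_np = np.where(u < 0.5, rng.exponential(np.exp(-2.0 * x)),
                        5.0 + rng.exponential(np.exp(2.0 * x)))
        nph = pd.DataFrame({"t": t_np, "e": np.ones(n, bool), "x": x})
        out_np = schoenfeld_ph_test(fit_cox(nph, "t", "e", ["x"]))
        assert out_ph.loc["x", "p"] > 0.01
        assert out_np.loc["x", "p"] < 1e-4


@pytest.fixture(scope="module")
def panel():
    return generate_score_panel(TruthParams(n_patients=800, seed=21)).analysis_panel()


class TestOutcomeModels:
    def test_model_a_estimates_protective_baseline_association(self, panel):
        fit = CoxOutcomeModel(panel, "A").fit()
        assert float(fit.hr["mos10_baseline"]) < 1.0
        assert fit.se_type == "model"

    def test_model_b_adjusts_for_baseline_covariates(self, panel):
        fit = CoxOutcomeModel(panel, "B").fit()
        assert "hfpsi_4" in fit.covariates
        assert float(fit.hr["hfpsi_4"]) > 1.0  # severity raises hazard

    def test_model_c_uses_lagged_cumulative_exposure_with_robust_se(self, panel):
        fit = CoxOutcomeModel(panel, "C").fit()
        assert fit.se_type == "cluster-robust"
        assert "cum_mos_lag10" in fit.covariates

    def test_model_c_recovers_truth_without_confounding(self):
        """Known exposure effect, no feedback: estimate within 2 MC SEs."""
        import math

        estimates = []
        for seed in range(6):
            params = TruthParams(
                n_patients=1500, seed=500 + seed,
                feedback_hfpsi_on_mos=0.0, feedback_mos_on_hfpsi=0.0,
                titration_mean_pp=0.0, titration_sd_pp=0.0, mos_noise_sd=0.0,
            )
            # MOS constant within patient, so the lagged cumulative mean
            # coincides with the exposure driving the hazard
            df = generate_score_panel(params).analysis_panel()
            fit = CoxOutcomeModel(df, "C").fit()
            estimates.append(float(fit.coef["cum_mos_lag10"]))
        mc_se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert np.mean(estimates) == pytest.approx(math.log(0.88), abs=2 * mc_se)
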