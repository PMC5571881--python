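"""Proportions, survival estimators, Cox regression, concordance, NRI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ironmark import (
    cox_fit,
    harrell_c,
    km_estimate,
    logrank_test,
    nri_unconditional,
    plan_sample_size,
    two_proportion_compare,
)
from ironmark.stats import analyze_cohort
from ironmark.synthetic import CohortSimParams, simulate_cohort


class TestTwoProportion:
    def test_symmetric_groups(self):
        pc = two_proportion_compare(10, 100, 10, 100)
        assert pc.diff == 0.0 and pc.z == 0.0 and pc.p_value == 1.0

    def test_antisymmetry(self):
        a = two_proportion_compare(30, 80, 45, 120)
        b = two_proportion_compare(45, 120, 30, 80)
        assert b.diff == pytest.approx(-a.diff, abs=1e-12)
        assert (b.ci_low, b.ci_high) == pytest.approx((-a.ci_high, -a.ci_low), abs=1e-12)
        assert b.p_value == pytest.approx(a.p_value, abs=1e-12)

    def test_ci_brackets_diff(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(5, 200, 2)
            k1, k2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            pc = two_proportion_compare(int(k1), int(n1), int(k2), int(n2))
            assert pc.ci_low <= pc.diff <= pc.ci_high
            assert 0 < pc.p_value <= 1

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        n1=st.integers(1, 500),
        n2=st.integers(1, 500),
        f1=st.floats(0, 1),
        f2=st.floats(0, 1),
    )
    def test_properties_hold_for_arbitrary_counts(self, n1, n2, f1, f2):
        k1, k2 = int(round(f1 * n1)), int(round(f2 * n2))
        a = two_proportion_compare(k1, n1, k2, n2)
        b = two_proportion_compare(k2, n2, k1, n1)
        assert a.ci_low <= a.diff <= a.ci_high
        assert 0 < a.p_value <= 1
        assert b.diff == pytest.approx(-a.diff, abs=1e-12)
        assert b.p_value == pytest.approx(a.p_value, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_compare(1, 0, 2, 10)
        with pytest.raises(ValueError):
            two_proportion_compare(11, 10, 2, 10)


class TestKaplanMeier:
    def test_three_subject_closed_form(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 0])
        s = dict(zip(curve.times, curve.survival))
        assert s[0.0] == 1.0
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[2.0] == pytest.approx(1 / 3)
        assert s[3.0] == pytest.approx(1 / 3)

    def test_no_events_survival_is_one(self):
        curve = km_estimate([5.0, 7.0, 9.0], [0, 0, 0])
        assert np.all(curve.survival == 1.0)

    def test_matches_empirical_survival_without_censoring(self, rng):
        times = rng.exponential(100.0, size=50).round(1)
        curve = km_estimate(times, np.ones(50, int))
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_nonincreasing_and_starts_at_one(self, rng):
        times = rng.exponential(100.0, 80)
        events = (rng.random(80) < 0.6).astype(int)
        curve = km_estimate(times, events)
        assert curve.survival[0] == 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [1, 1])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [1.0, 2.0, 3.0, 4.0] * 2
        events = [1, 1, 0, 1] * 2
        groups = ["A"] * 4 + ["B"] * 4
        chi2, p = logrank_test(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_tiny_worked_example_matches_hand_computation(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 0])
        groups = np.array(["A", "A", "B", "B"])
        # hand-computed observed-minus-expected with hypergeometric variance
        o_minus_e, var = 0.0, 0.0
        for t in times[events == 1]:
            at_risk = times >= t
            n, n_a = at_risk.sum(), (at_risk & (groups == "A")).sum()
            d = ((times == t) & (events == 1)).sum()
            o_minus_e += ((times == t) & (events == 1) & (groups == "A")).sum() - d * n_a / n
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        expected_chi2 = o_minus_e**2 / var
        chi2, _ = logrank_test(times, events, groups)
        assert chi2 == pytest.approx(expected_chi2, rel=1e-9)

    def test_power_under_strong_alternative(self):
        rejections = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            group = np.repeat([0, 1], 250)
            lam = np.where(group == 1, 2.0, 1.0) * 1e-2
            t = rng.exponential(1 / lam)
            c = np.minimum(t, 100.0)
            e = (t <= 100.0).astype(int)
            _, p = logrank_test(c, e, group)
            rejections += p < 0.05
        assert rejections / 200 > 0.90

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([1, 2], [1, 1], ["A", "A"])


def _brute_force_cox_beta(times, events, x, lo=-4.0, hi=4.0, step=1e-5):
    """Grid maximiser of the written-out partial likelihood (no ties)."""
    betas = np.arange(lo, hi, step)
    ll = np.zeros_like(betas)
    for i in np.nonzero(events)[0]:
        risk = times >= times[i]
        ll += x[i] * betas - np.log(
            np.exp(np.outer(betas, x[risk])).sum(axis=1)
        )
    return betas[np.argmax(ll)]


class TestCox:
    def _frame(self, times, events, x):
        return pd.DataFrame(
            {"event_time_days": times, "event": events, "x": x}
        )

    def test_six_subject_binary_covariate_matches_grid_search(self):
        times = np.array([3.0, 5.0, 7.0, 11.0, 13.0, 17.0])
        events = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        fit = cox_fit(self._frame(times, events, x), ["x"])
        expected = _brute_force_cox_beta(times, events, x)
        assert fit.coef[0] == pytest.approx(expected, abs=1e-4)

    def test_null_covariate_coefficient_near_zero(self, rng):
        n = 1000
        times = rng.exponential(100.0, n)
        events = (rng.random(n) < 0.7).astype(int)
        x = rng.permutation(np.repeat([0.0, 1.0], n // 2))
        fit = cox_fit(self._frame(times, events, x), ["x"])
        assert abs(fit.coef[0]) < 0.1

    def test_log_likelihood_nondecreasing_and_converged(self, rng):
        n = 400
        x = rng.normal(size=n)
        times = rng.exponential(np.exp(-0.5 * x) * 100.0).round(0) + 1  # ties
        events = (rng.random(n) < 0.8).astype(int)
        fit = cox_fit(self._frame(times, events, x), ["x"])
        assert np.all(np.diff(fit.ll_path) >= -1e-9)
        assert fit.iterations < 100 and not fit.separation_flag

    def test_matches_lifelines_with_ties(self, rng):
        from lifelines import CoxPHFitter

        n = 300
        df = pd.DataFrame(
            {
                "a": rng.normal(size=n),
                "b": (rng.random(n) < 0.5).astype(float),
            }
        )
        times = rng.exponential(100 * np.exp(-0.4 * df["a"] - 0.3 * df["b"]))
        df["event_time_days"] = np.round(times / 10) * 10 + 10  # heavy ties
        df["event"] = (rng.random(n) < 0.75).astype(int)
        fit = cox_fit(df, ["a", "b"])
        cph = CoxPHFitter().fit(
            df[["event_time_days", "event", "a", "b"]], "event_time_days", "event"
        )
        np.testing.assert_allclose(fit.coef, cph.params_.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-6)
        assert fit.c_statistic == pytest.approx(cph.concordance_index_, abs=1e-9)

    def test_hazard_ratio_recovery_on_calibrated_cohort(self):
        cohort = simulate_cohort(CohortSimParams(n_patients=10_000, seed=42))
        fit = cox_fit(cohort.patients, ["baseline_diameter_mm", "current_smoker"])
        assert 1.06 <= fit.hr[0] <= 1.09  # generative value 1.077 / mm
        assert fit.ci_low[0] <= 1.077 <= fit.ci_high[0]

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cox_fit(self._frame([1.0, 2.0], [0, 0], [0.0, 1.0]), ["x"])


class TestHarrellC:
    def test_perfect_ordering(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        assert harrell_c([4, 3, 2, 1], times, [1, 1, 1, 1]) == 1.0
        assert harrell_c([1, 2, 3, 4], times, [1, 1, 1, 1]) == 0.0

    def test_all_tied_scores_half(self):
        assert harrell_c([1, 1, 1], [1.0, 2.0, 3.0], [1, 1, 1]) == 0.5

    def test_matches_exhaustive_pair_enumeration(self, rng):
        n = 30
        times = rng.exponential(50, n).round(0)
        events = (rng.random(n) < 0.6).astype(int)
        scores = rng.normal(size=n)
        conc = usable = 0.0
        for i in range(n):
            for j in range(n):
                if i == j or events[i] != 1:
                    continue
                if times[i] < times[j] or (times[i] == times[j] and events[j] == 0):
                    usable += 1
                    if scores[i] > scores[j]:
                        conc += 1
                    elif scores[i] == scores[j]:
                        conc += 0.5
        assert harrell_c(scores, times, events) == pytest.approx(conc / usable, abs=1e-12)

    def test_no_usable_pairs(self):
        with pytest.raises(ValueError, match="usable"):
            harrell_c([1.0, 2.0], [5.0, 5.0], [0, 0])


class TestNRI:
    def test_self_comparison_is_zero(self, rng):
        n = 200
        risk = rng.random(n)
        times = rng.exponential(500, n)
        events = (rng.random(n) < 0.5).astype(int)
        res = nri_unconditional(risk, risk, times, events, 365.0, n_bootstrap=200, seed=1)
        assert res.nri_overall == 0.0
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_oracle_marker_gives_two_hundred_percent(self, rng):
        n = 100
        times = np.where(rng.random(n) < 0.4, 100.0, 900.0)
        events = (times < 365).astype(int)
        base = np.full(n, 0.5)
        ext = events.astype(float)
        res = nri_unconditional(base, ext, times, events, 365.0, n_bootstrap=100, seed=2)
        assert res.nri_overall == pytest.approx(200.0)
        assert res.event_component == pytest.approx(100.0)
        assert res.nonevent_component == pytest.approx(100.0)

    def test_components_bounded(self, rng):
        n = 300
        times = rng.exponential(600, n)
        events = (rng.random(n) < 0.6).astype(int)
        res = nri_unconditional(
            rng.random(n), rng.random(n), times, events, 365.0, n_bootstrap=100, seed=3
        )
        assert -100.0 <= res.event_component <= 100.0
        assert -100.0 <= res.nonevent_component <= 100.0
        assert -200.0 <= res.nri_overall <= 200.0

    def test_risks_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="risks"):
            nri_unconditional([1.2], [0.5], [10.0], [1], 5.0)

    def test_no_events_before_horizon_rejected(self):
        with pytest.raises(ValueError, match="events"):
            nri_unconditional([0.5], [0.6], [100.0], [0], 50.0)


class TestPlanSampleSize:
    def test_trial_design_values(self):
        n_analysis, n_recruit = plan_sample_size(130, 0.41, 0.10)
        assert n_analysis == 317
        assert n_recruit == 353

    def test_no_dropout_certain_event(self):
        assert plan_sample_size(100, 1.0, 0.0) == (100, 100)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            plan_sample_size(100, 0.0, 0.1)


class TestAnalyzeCohort:
    def test_bundle_counts_and_blocks(self):
        cohort = simulate_cohort(CohortSimParams(n_patients=342, seed=5))
        bundle = analyze_cohort(cohort, n_bootstrap=200, seed=5)
        c = bundle["counts"]
        assert c["enhanced"] + c["nonenhanced"] + c["indeterminate"] == c["total"] == 342
        s = bundle["strata"]
        assert s["n_small"] + s["n_large"] == 342
        for key in ("growth", "primary_endpoint", "logrank", "km", "cox", "nri"):
            assert key in bundle

    def test_indeterminate_excluded_from_denominators(self):
        cohort = simulate_cohort(CohortSimParams(n_patients=100, seed=6))
        calls = cohort.patients[["patient_id"]].copy()
        calls["status"] = cohort.patients["observed_status"]
        calls.loc[:4, "status"] = "indeterminate"
        bundle = analyze_cohort(cohort, calls, n_bootstrap=100, seed=6)
        c = bundle["counts"]
        assert c["indeterminate"] == 5
        pe = bundle["primary_endpoint"]
        assert pe["n1"] + pe["n2"] == 95

    def test_null_cohort_rarely_significant(self):
        # enhancement independent of outcome: primary comparison should not
        # reject much more often than alpha
        hits = 0
        for seed in range(20):
            cohort = simulate_cohort(
                CohortSimParams(
                    n_patients=342,
                    seed=seed,
                    enhancement_beta_diameter=0.0,
                    enhancement_beta_smoking=0.0,
                    growth_enhancement_shift=0.0,
                )
            )
            bundle = analyze_cohort(cohort, n_bootstrap=50, seed=seed)
            hits += bundle["primary_endpoint"]["p_value"] < 0.05
        assert hits <= 4
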