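import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from epicirc.simulate import simulate_survival
from epicirc.survival import (
    SurvivalError,
    cox_univariate,
    km_estimate,
    logrank,
    median_split,
    survival_fit,
)


def records(times, events, groups=None, expression=None):
    frame = pd.DataFrame({"time": times, "event": events})
    if groups is not None:
        frame["group"] = groups
    if expression is not None:
        frame["expression"] = expression
    return frame


class TestMedianSplit:
    def test_even_n_distinct_values_split_in_half(self):
        r = records([1] * 10, [1] * 10, expression=list(range(1, 11)))
        out = median_split(r)
        assert (out["group"] == "high").sum() == 5
        assert (out["group"] == "low").sum() == 5
        assert set(out.loc[out["expression"] > 5.5, "group"]) == {"high"}

    def test_odd_n_median_subject_goes_low(self):
        r = records([1] * 5, [1] * 5, expression=[1, 2, 3, 4, 5])
        out = median_split(r)
        assert out.loc[out["expression"] == 3, "group"].iloc[0] == "low"
        assert (out["group"] == "high").sum() == 2

    def test_ties_at_median_all_go_low(self):
        r = records([1] * 6, [1] * 6, expression=[1, 2, 2, 2, 3, 4])
        out = median_split(r)
        # median is 2; the three tied subjects plus the 1 all land low
        assert (out["group"] == "low").sum() == 4
        assert (out["group"] == "high").sum() == 2

    def test_constant_marker_errors(self):
        r = records([1] * 4, [1] * 4, expression=[2, 2, 2, 2])
        with pytest.raises(SurvivalError, match="identical"):
            median_split(r)


class TestKaplanMeier:
    def test_all_censored_is_constant_one(self):
        s = km_estimate(records([5, 8, 12], [0, 0, 0]))
        assert (s.values == 1.0).all()

    def test_two_events_no_censoring(self):
        s = km_estimate(records([1, 2], [1, 1]))
        assert s.loc[1] == pytest.approx(0.5)
        assert s.loc[2] == pytest.approx(0.0)

    def test_textbook_mixed_censoring_table(self):
        # events at 1, 3, 4, 6; censored at 2 and 5:
        # S(1)=5/6, S(3)=5/6*3/4=0.625, S(4)=0.625*2/3=0.41667, S(6)=0
        s = km_estimate(records([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1]))
        assert s.loc[1] == pytest.approx(5 / 6)
        assert s.loc[3] == pytest.approx(0.625)
        assert s.loc[4] == pytest.approx(5 / 12)
        assert s.loc[6] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, size=40)
        s = km_estimate(records(t, [1] * 40))
        for time in s.index[1:]:
            assert s.loc[time] == pytest.approx((t > time).mean())

    def test_km_is_nonincreasing_and_starts_at_one(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, size=30)
        e = rng.random(30) < 0.7
        s = km_estimate(records(t, e.astype(int)))
        assert s.iloc[0] == 1.0
        assert (np.diff(s.values) <= 1e-12).all()


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        base_t, base_e = [1, 2, 3, 4], [1, 0, 1, 1]
        r = records(base_t * 2, base_e * 2, groups=["high"] * 4 + ["low"] * 4)
        chi2, p = logrank(r)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_event_closed_form(self):
        # one event in group A with equal risk sets of 3: O-E = 1 - 1/2,
        # V = n_A n_B / n^2 = 1/4, chi2 = 0.25/0.25 = 1
        r = records([1, 5, 5, 5, 5, 5], [1, 0, 0, 0, 0, 0],
                    groups=["high"] * 3 + ["low"] * 3)
        chi2, p = logrank(r)
        assert chi2 == pytest.approx(1.0)
        assert p == pytest.approx(stats.chi2.sf(1.0, 1))

    def test_invariant_to_group_relabeling(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 20)
        e = (rng.random(20) < 0.8).astype(int)
        g = ["high"] * 10 + ["low"] * 10
        swapped = ["low" if x == "high" else "high" for x in g]
        assert logrank(records(t, e, g)) == pytest.approx(logrank(records(t, e, swapped)))

    def test_type_I_error_calibration_under_equal_hazards(self):
        rng = np.random.default_rng(4)
        rejections = 0
        reps = 500
        for _ in range(reps):
            t = rng.exponential(100, 200)
            c = rng.exponential(300, 200)
            time = np.minimum(t, c)
            event = (t <= c).astype(int)
            g = np.where(rng.random(200) < 0.5, "high", "low")
            if event.sum() == 0 or len(set(g)) < 2:
                continue
            _, p = logrank(records(time, event, list(g)))
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_no_events_errors(self):
        r = records([1, 2, 3, 4], [0, 0, 0, 0], groups=["high", "high", "low", "low"])
        with pytest.raises(SurvivalError):
            logrank(r)


def partial_likelihood_oracle(times, events, x):
    """Brute-force Efron partial-likelihood maximizer for one binary covariate."""
    times, events, x = map(np.asarray, (times, events, x))

    def neg_loglik(beta):
        ll = 0.0
        for t in np.unique(times[events == 1]):
            tied = (times == t) & (events == 1)
            risk = times >= t
            d = tied.sum()
            theta_risk = np.exp(beta * x[risk]).sum()
            theta_tied = np.exp(beta * x[tied]).sum()
            ll += beta * x[tied].sum()
            for j in range(d):
                ll -= np.log(theta_risk - j / d * theta_tied)
        return -ll

    res = optimize.minimize_scalar(
        neg_loglik, bounds=(-10, 10), method="bounded", options={"xatol": 1e-10}
    )
    return res.x


class TestCoxUnivariate:
    def test_two_subject_tied_events_have_zero_coefficient(self):
        # both events at the same time, one per group: the Efron partial
        # likelihood 2e^b/(1+e^b)^2 is maximized at b = 0 (HR = 1)
        r = records([5, 5], [1, 1], groups=["high", "low"])
        r = pd.concat([r, records([9, 9], [0, 0], groups=["high", "low"])])
        fit = cox_univariate(r)
        assert fit.coef == pytest.approx(0.0, abs=1e-6)
        assert fit.hr == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_partial_likelihood_on_toys(self):
        t = [1, 2, 3, 4, 5, 6, 7, 8]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        g = ["high", "low", "high", "low", "high", "low", "high", "low"]
        fit = cox_univariate(records(t, e, g))
        x = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        beta = partial_likelihood_oracle(t, e, x)
        assert fit.coef == pytest.approx(beta, abs=1e-4)

    def test_reciprocal_hr_under_group_swap(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 30)
        e = (rng.random(30) < 0.8).astype(int)
        g = ["high"] * 15 + ["low"] * 15
        swapped = ["low" if x == "high" else "high" for x in g]
        f1 = cox_univariate(records(t, e, g))
        f2 = cox_univariate(records(t, e, swapped))
        assert f1.hr * f2.hr == pytest.approx(1.0, rel=1e-6)
        assert f1.ci_low * f2.ci_high == pytest.approx(1.0, rel=1e-6)

    def test_null_labels_give_hr_near_one_within_ci(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(10, 400)
        e = np.ones(400, int)
        g = np.where(rng.random(400) < 0.5, "high", "low")
        fit = cox_univariate(records(t, e, list(g)))
        assert fit.ci_low < 1.0 < fit.ci_high
        assert 0.7 < fit.hr < 1.4

    def test_complete_separation_is_flagged_unbounded(self):
        # every event in the high group, all low subjects censored late
        r = records([1, 2, 3, 10, 10, 10], [1, 1, 1, 0, 0, 0],
                    groups=["high"] * 3 + ["low"] * 3)
        fit = cox_univariate(r)
        assert fit.separation
        assert fit.ci_high == np.inf and fit.ci_low == 0.0


class TestSurvivalFitAndGenerator:
    def test_fit_bundles_split_km_logrank_cox(self):
        cohort = simulate_survival(n=120, true_hr=2.4, censor_rate=0.2, seed=7)
        fit = survival_fit(cohort, marker="m")
        assert fit.n_high + fit.n_low == 120
        assert fit.km_high.iloc[0] == 1.0 and fit.km_low.iloc[0] == 1.0
        assert 0 < fit.logrank_p < 1
        assert fit.cox.ci_low < fit.cox.hr < fit.cox.ci_high

    def test_zero_censor_rate_keeps_every_event(self):
        cohort = simulate_survival(n=50, true_hr=1.0, censor_rate=0.0, seed=8)
        assert (cohort["event"] == 1).all()

    def test_censor_rate_is_approximately_achieved(self):
        cohort = simulate_survival(n=4000, true_hr=2.0, censor_rate=0.3, seed=9)
        assert (1 - cohort["event"]).mean() == pytest.approx(0.3, abs=0.03)

    def test_null_hazard_ratio_logrank_rejects_at_alpha(self):
        rng = np.random.default_rng(10)
        rejections = 0
        reps = 200
        for i in range(reps):
            cohort = simulate_survival(
                n=100, true_hr=1.0, censor_rate=0.1, seed=int(rng.integers(2**31))
            )
            fit = survival_fit(cohort)
            rejections += fit.logrank_p < 0.05
        assert 0.01 <= rejections / reps <= 0.09

    def test_hr_recovery_at_study_scale(self):
        rng = np.random.default_rng(11)
        hrs = []
        for _ in range(40):
            cohort = simulate_survival(
                n=300, true_hr=2.4, censor_rate=0.2, seed=int(rng.integers(2**31))
            )
            hrs.append(survival_fit(cohort).cox.hr)
        assert 2.1 <= float(np.median(hrs)) <= 2.7
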