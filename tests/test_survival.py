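"""Kaplan-Meier, log-rank, Cox partial likelihood and fixed-effect meta-analysis."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.meta_analysis import combine_effects

from regulink.survival import (
    cox_fit,
    km_curve,
    logrank_test,
    median_stratify,
    meta_fixed_effect,
)
from regulink.synthetic import SimulationConfig, simulate_survival


def clin(times, events, **extra):
    return pd.DataFrame({"time": times, "event": events, **extra},
                        index=[f"S{i}" for i in range(len(times))])


class TestKM:
    def test_all_censored_flat_at_one(self):
        km = km_curve(clin([3, 5, 8], [0, 0, 0]))
        assert km.at(100.0) == 1.0

    def test_single_event_steps_to_zero(self):
        km = km_curve(clin([5.0], [1]))
        assert km.at(4.999) == 1.0
        assert km.at(5.0) == 0.0

    def test_nonpositive_time_rejected_with_id(self):
        with pytest.raises(ValueError, match="S1"):
            km_curve(clin([3, 0.0, 2], [1, 1, 1]))

    def test_matches_hand_product_limit(self, rng):
        times = rng.exponential(10, size=10).round(2) + 0.1
        events = rng.integers(0, 2, size=10)
        km = km_curve(clin(times, events))
        # independent product-limit computation
        order = np.argsort(times)
        t_sorted, e_sorted = times[order], events[order]
        surv = 1.0
        for i, (t, e) in enumerate(zip(t_sorted, e_sorted)):
            at_risk = (t_sorted >= t).sum()
            if e:
                surv *= 1 - 1 / at_risk
            assert km.at(t) == pytest.approx(surv, abs=1e-12)

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(10, size=40) + 0.1
        km = km_curve(clin(times, np.ones(40, dtype=int)))
        for q in (0.25, 0.5, 0.75):
            t = np.quantile(times, q)
            assert km.at(t) == pytest.approx((times > t).mean(), abs=1e-12)


class TestLogrank:
    def test_hand_computed_two_group_statistic(self):
        # A events at 1, 2; B events at 3, 4: O_A=2, E_A=5/6, Var=17/36 -> chi2=49/17
        d = clin([1, 2, 3, 4], [1, 1, 1, 1], group=["A", "A", "B", "B"])
        res = logrank_test(d, "group")
        assert res.chi2 == pytest.approx(49 / 17, rel=1e-9)
        assert res.df == 1

    def test_identical_groups_null(self):
        d = clin([1, 2, 1, 2], [1, 1, 1, 1], group=["A", "A", "B", "B"])
        assert logrank_test(d, "group").chi2 == pytest.approx(0.0, abs=1e-12)

    def test_p_is_chi2_survival_function(self):
        d = clin([1, 2, 3, 4], [1, 1, 1, 1], group=["A", "A", "B", "B"])
        res = logrank_test(d, "group")
        assert res.p == pytest.approx(stats.chi2.sf(res.chi2, df=1), rel=1e-12)

    def test_symmetric_under_label_swap(self, rng):
        d = clin(rng.exponential(10, 30) + 0.1, rng.integers(0, 2, 30),
                 group=rng.choice(["A", "B"], 30))
        swapped = d.assign(group=d.group.map({"A": "B", "B": "A"}))
        assert logrank_test(d, "group").chi2 == pytest.approx(
            logrank_test(swapped, "group").chi2)

    def test_single_group_rejected(self):
        d = clin([1, 2], [1, 1], group=["A", "A"])
        with pytest.raises(ValueError, match="two"):
            logrank_test(d, "group")


def breslow_mle_1d(df, covariate, bounds=(-5, 5)):
    """Independent grid-search maximizer of the Breslow log partial likelihood."""
    t = df["time"].to_numpy()
    d = df["event"].to_numpy().astype(bool)
    x = df[covariate].to_numpy(dtype=float)
    order = np.argsort(-t)
    xs, ds = x[order], d[order]

    def nll(b):
        cum = np.logaddexp.accumulate(b * xs)
        return -(b * xs[ds] - cum[ds]).sum()

    return minimize_scalar(nll, bounds=bounds, method="bounded",
                           options={"xatol": 1e-10}).x


class TestCox:
    def test_four_subject_fixture_matches_grid_search(self):
        d = clin([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], x=[0.0, 1.0, 0.0, 1.0])
        fit = cox_fit(d, ["x"])
        assert fit.summary.loc["x", "lnHR"] == pytest.approx(breslow_mle_1d(d, "x"), abs=1e-6)

    def test_null_simulation_recovery(self):
        scores = pd.Series(np.random.default_rng(1).normal(size=2000))
        surv = simulate_survival(scores, SimulationConfig(surv_lnHR=0.0, seed=30))
        fit = cox_fit(surv, ["score"])
        assert abs(fit.summary.loc["score", "lnHR"]) < 0.1

    def test_planted_lnhr_recovery_and_grid_search_agreement(self):
        scores = pd.Series(np.random.default_rng(2).standard_normal(2000))
        surv = simulate_survival(scores, SimulationConfig(surv_lnHR=0.7, censor_rate=0.2, seed=31))
        fit = cox_fit(surv, ["score"])
        est = fit.summary.loc["score", "lnHR"]
        assert abs(est - 0.7) < 0.1
        assert est == pytest.approx(breslow_mle_1d(surv, "score"), abs=1e-5)

    def test_ci_brackets_hr(self):
        d = clin([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 1, 1], x=[0.2, 1.0, 0.1, 0.9, 0.3, 1.1])
        fit = cox_fit(d, ["x"])
        row = fit.summary.loc["x"]
        assert row.ci95_low <= row.HR <= row.ci95_high

    def test_agrees_with_logrank_direction(self, rng):
        for _ in range(20):
            n = 60
            x = rng.integers(0, 2, n)
            scores = pd.Series(x.astype(float))
            surv = simulate_survival(scores, SimulationConfig(
                surv_lnHR=float(rng.choice([0.8, -0.8])), censor_rate=0.1,
                seed=int(rng.integers(1 << 30))))
            surv["grp"] = np.where(x == 1, "hi", "lo")
            fit = cox_fit(surv, ["score"])
            lr = logrank_test(surv, "grp")
            if lr.p < 0.01:  # where the log-rank is clear, Cox must agree in direction
                assert (fit.summary.loc["score", "p"] < 0.1)

    def test_agrees_with_lifelines_on_continuous_times(self, rng):
        # no ties: Breslow and Efron coincide, so lifelines (Efron) is an
        # independent check of the whole fit including standard errors
        from lifelines import CoxPHFitter
        d = clin(rng.exponential(20, 80) + rng.uniform(0, 1, 80),
                 rng.integers(0, 2, 80) | (np.arange(80) < 5),
                 x=rng.normal(size=80), y=rng.integers(0, 2, 80).astype(float))
        fit = cox_fit(d, ["x", "y"])
        cph = CoxPHFitter()
        cph.fit(d[["time", "event", "x", "y"]], "time", "event")
        for c in ("x", "y"):
            assert fit.summary.loc[c, "lnHR"] == pytest.approx(cph.params_[c], abs=1e-4)
            assert fit.summary.loc[c, "se"] == pytest.approx(
                cph.standard_errors_[c], rel=1e-3)

    def test_efron_ties_match_lifelines(self, rng):
        times = np.repeat([1.0, 2.0, 3.0, 5.0, 8.0], 6)
        d = clin(times, rng.integers(0, 2, 30) | (np.arange(30) % 7 == 0),
                 x=rng.normal(size=30))
        from lifelines import CoxPHFitter
        fit = cox_fit(d, ["x"], ties="efron")
        cph = CoxPHFitter()
        cph.fit(d[["time", "event", "x"]], "time", "event")
        assert fit.summary.loc["x", "lnHR"] == pytest.approx(cph.params_["x"], abs=1e-4)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cox_fit(clin([1, 2], [0, 0], x=[0.0, 1.0]), ["x"])

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(clin([1, 2], [1, 1], x=[1.0, 1.0]), ["x"])


class TestMedianStratify:
    def test_even_split(self):
        res = median_stratify(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
        assert res.median == 2.5
        assert res.labels.tolist() == ["low", "low", "high", "high"]

    def test_ties_at_median_go_high(self):
        res = median_stratify(pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd")))
        assert res.labels.tolist() == ["low", "high", "high", "high"]

    def test_odd_n(self):
        res = median_stratify(pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        assert res.n_low == 1 and res.n_high == 2

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            median_stratify(pd.Series([2.0, 2.0, 2.0]))


class TestMeta:
    def test_symmetric_studies(self):
        res = meta_fixed_effect([(0.5, 0.2), (0.5, 0.2)])
        assert res.pooled_lnHR == pytest.approx(0.5)
        assert res.se == pytest.approx(0.2 / np.sqrt(2))
        assert res.i2 == 0.0

    def test_precise_study_dominates(self):
        res = meta_fixed_effect([(1.0, 0.01), (-3.0, 10.0)])
        assert res.pooled_lnHR == pytest.approx(1.0, abs=1e-3)

    def test_matches_hand_weighted_mean_and_statsmodels(self, rng):
        lnhr = rng.normal(0.3, 0.2, size=5)
        se = rng.uniform(0.1, 0.5, size=5)
        res = meta_fixed_effect(list(zip(lnhr, se)))
        w = 1 / se**2
        assert res.pooled_lnHR == pytest.approx((w * lnhr).sum() / w.sum(), rel=1e-12)
        sm = combine_effects(lnhr, se**2).summary_frame().loc["fixed effect"]
        assert res.pooled_lnHR == pytest.approx(sm["eff"], rel=1e-9)

    def test_high_heterogeneity_warns(self):
        with pytest.warns(UserWarning, match="I²"):
            meta_fixed_effect([(2.0, 0.1), (-2.0, 0.1)])

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError, match="standard errors"):
            meta_fixed_effect([(0.5, 0.0), (0.4, 0.1)])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.floats(-2, 2), st.floats(0.05, 2)), min_size=2, max_size=8))
    def test_pooled_within_convex_hull(self, studies):
        res = meta_fixed_effect(studies)
        lnhrs = [s[0] for s in studies]
        assert min(lnhrs) - 1e-12 <= res.pooled_lnHR <= max(lnhrs) + 1e-12
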