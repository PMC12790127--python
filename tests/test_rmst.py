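import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.utils import restricted_mean_survival_time

from frailcurve import (RMSTFrailtyCox, fit_frailty, km_estimate, rmst_km,
                        rmst_difference, rmst_frailty)
from frailcurve.rmst import (HorizonError, default_tau,
                             fit_rmst_frailty_regression, truncate_at_tau)


class TestRmstKM:
    def test_hand_example_no_censoring(self):
        # three subjects, events at 1, 2, 3: S = 2/3, 1/3, 0 and
        # RMST(3) = 1 + 2/3 + 1/3 = 2 exactly
        curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert rmst_km(curve, 3.0).estimate == pytest.approx(2.0, abs=1e-12)
        assert rmst_km(curve, 2.0).estimate == pytest.approx(1 + 2 / 3,
                                                             abs=1e-12)
        # tau before the first event: area is just tau
        assert rmst_km(curve, 0.5).estimate == pytest.approx(0.5, abs=1e-12)

    def test_hand_example_with_censoring(self):
        # times 1..5, events 1,1,0,1,0: S = .8, .6, .3
        curve = km_estimate([1, 2, 3, 4, 5], [1, 1, 0, 1, 0])
        assert rmst_km(curve, 3.0).estimate == pytest.approx(1 + 0.8 + 0.6,
                                                             abs=1e-12)
        assert rmst_km(curve, 5.0).estimate == pytest.approx(
            1 + 0.8 + 2 * 0.6 + 0.3, abs=1e-12)

    def test_no_censoring_equals_truncated_mean(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10.0, 300)
        curve = km_estimate(t, np.ones(300, dtype=int))
        for tau in (2.0, 8.0, float(t.max())):
            expected = np.minimum(t, tau).mean()
            assert rmst_km(curve, tau).estimate == pytest.approx(expected,
                                                                 abs=1e-10)

    def test_matches_lifelines_estimate(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10.0, 200)
        c = rng.exponential(25.0, 200)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        tau = 12.0
        kmf = KaplanMeierFitter().fit(time, event)
        expected = restricted_mean_survival_time(kmf, t=tau)
        res = rmst_km(km_estimate(time, event), tau)
        assert res.estimate == pytest.approx(float(expected), abs=1e-9)

    def test_se_no_censoring_closed_form(self):
        # without censoring the Greenwood-type RMST variance collapses to
        # the plain variance of the truncated lifetime over n
        rng = np.random.default_rng(5)
        n = 400
        t = rng.exponential(10.0, n)
        tau = 12.0
        res = rmst_km(km_estimate(t, np.ones(n, dtype=int)), tau)
        expected = np.minimum(t, tau).std(ddof=0) / np.sqrt(n)
        assert res.se == pytest.approx(expected, rel=1e-10)

    def test_se_calibrated_under_censoring(self):
        # Monte Carlo: the mean reported SE should track the sampling sd
        # of the estimator across replicates
        tau = 12.0
        ests, ses = [], []
        for s in range(200):
            rng = np.random.default_rng(1000 + s)
            t = rng.exponential(10.0, 200)
            c = rng.exponential(25.0, 200)
            time, event = np.minimum(t, c), (t <= c).astype(int)
            res = rmst_km(km_estimate(time, event), tau)
            ests.append(res.estimate)
            ses.append(res.se)
        assert np.mean(ses) == pytest.approx(np.std(ests, ddof=1), rel=0.15)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10.0, 100)
        res = rmst_km(km_estimate(t, np.ones(100, dtype=int)), 8.0)
        lo, hi = res.ci()
        assert lo < res.estimate < hi
        lo99, hi99 = res.ci(0.99)
        assert lo99 < lo and hi < hi99

    def test_horizon_errors(self):
        curve = km_estimate([1.0, 2.0], [1, 1])
        with pytest.raises(HorizonError):
            rmst_km(curve, 0.0)
        with pytest.raises(HorizonError):
            rmst_km(curve, 2.5)


class TestRmstFrailty:
    def test_theta_zero_reduces_to_baseline_power(self, small_cohort):
        model = fit_frailty(small_cohort, theta=0.0)
        row = small_cohort.iloc[0]
        res = rmst_frailty(model, row, tau=30.0)
        base = model.baseline_survival()
        risk = float(np.exp(model._linear_predictor(small_cohort.iloc[[0]]))[0])
        from frailcurve.rmst import _step_integral
        expected = _step_integral(base.times, base.survival ** risk, 30.0)
        assert res.estimate == pytest.approx(expected, abs=1e-12)

    def test_decreasing_in_risk(self, small_cohort):
        model = fit_frailty(small_cohort, theta=0.5)
        lo = small_cohort.iloc[0].copy()
        hi = lo.copy()
        lo["age"], hi["age"] = 30.0, 90.0  # positive age log-HR in the DGP
        # higher linear predictor -> lower survival -> smaller area
        if model.coef_["age"] > 0:
            assert rmst_frailty(model, hi, 30.0).estimate < \
                rmst_frailty(model, lo, 30.0).estimate

    def test_bounded_by_tau(self, small_cohort):
        model = fit_frailty(small_cohort, theta=0.25)
        res = rmst_frailty(model, small_cohort.iloc[3], tau=20.0)
        assert 0.0 < res.estimate <= 20.0

    def test_horizon_error(self, small_cohort):
        model = fit_frailty(small_cohort, theta=0.25)
        with pytest.raises(HorizonError):
            rmst_frailty(model, small_cohort.iloc[0],
                         tau=small_cohort["time"].max() * 2)


class TestRmstDifference:
    @staticmethod
    def _two_group_frame(rate_b, seed, n=120):
        rng = np.random.default_rng(seed)
        t = np.concatenate([rng.exponential(1 / 0.05, n),
                            rng.exponential(1 / rate_b, n)])
        return pd.DataFrame({
            "time": t, "event": np.ones(2 * n, dtype=int),
            "grp": np.repeat(["a", "b"], n),
            "operator_id": np.tile(np.repeat([f"P{i}" for i in range(8)],
                                             n // 8), 2),
        })

    def test_separated_groups(self):
        df = self._two_group_frame(rate_b=0.2, seed=3)
        est, (lo, hi), results = rmst_difference(df, "grp", tau=15.0,
                                                 n_boot=200, seed=0)
        # group b has four times the hazard: rmst(b) - rmst(a) < 0
        assert est < 0
        assert lo < hi
        assert hi < 0  # CI excludes zero
        assert [r.group for r in results] == ["a", "b"]
        assert est == pytest.approx(results[1].estimate - results[0].estimate)

    def test_deterministic_given_seed(self):
        df = self._two_group_frame(rate_b=0.08, seed=4)
        a = rmst_difference(df, "grp", tau=10.0, n_boot=50, seed=11)
        b = rmst_difference(df, "grp", tau=10.0, n_boot=50, seed=11)
        assert a[0] == b[0] and a[1] == b[1]

    def test_needs_two_groups(self):
        df = self._two_group_frame(rate_b=0.05, seed=5)
        df["grp"] = "a"
        with pytest.raises(ValueError):
            rmst_difference(df, "grp", tau=5.0, n_boot=10)


class TestTruncation:
    def test_truncate_at_tau(self):
        df = pd.DataFrame({"time": [1.0, 5.0, 9.0], "event": [1, 0, 1]})
        out = truncate_at_tau(df, 6.0)
        np.testing.assert_allclose(out["time"], [1.0, 5.0, 6.0])
        np.testing.assert_array_equal(out["event"], [1, 0, 0])
        # input frame untouched
        assert df["time"].iloc[2] == 9.0

    def test_rmst_frailty_cox_equals_manual_truncation(self, small_cohort):
        tau = float(np.quantile(small_cohort["time"], 0.8))
        a = RMSTFrailtyCox(theta=0.3, tau=tau).fit(small_cohort)
        b = fit_frailty(truncate_at_tau(small_cohort, tau), theta=0.3)
        np.testing.assert_allclose(a.coef_.to_numpy(), b.coef_.to_numpy(),
                                   atol=1e-10)
        assert a.tau_ == tau

    def test_tau_none_uses_max_time(self, small_cohort):
        model = fit_rmst_frailty_regression(small_cohort, theta=0.2)
        assert model.tau_ == small_cohort["time"].max()

    def test_no_events_after_truncation(self, small_cohort):
        with pytest.raises(HorizonError):
            RMSTFrailtyCox(theta=0.2,
                           tau=small_cohort["time"].min() / 2).fit(small_cohort)


def test_default_tau(small_cohort):
    assert default_tau(small_cohort) == small_cohort["time"].max()
    per_center = small_cohort.groupby("center_id")["time"].max().min()
    assert default_tau(small_cohort, "center_id") == per_center
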