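import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from frailcurve import (ClusteredCox, GammaFrailtyCox, fit_cox, fit_frailty,
                        km_estimate, logrank_test)
from frailcurve.survival import SingularDesignError, SurvivalCurve


class TestKaplanMeier:
    def test_hand_example(self):
        # times 1..5, events 1,1,0,1,0:
        # S(1) = 4/5, S(2) = 4/5 * 3/4 = 3/5, S(4) = 3/5 * 1/2 = 3/10
        curve = km_estimate([1, 2, 3, 4, 5], [1, 1, 0, 1, 0])
        np.testing.assert_allclose(curve.times, [1.0, 2.0, 4.0])
        np.testing.assert_allclose(curve.survival, [0.8, 0.6, 0.3], atol=1e-12)
        assert curve(0.5) == 1.0
        assert curve(1.0) == pytest.approx(0.8)
        assert curve(3.9) == pytest.approx(0.6)
        assert curve(100.0) == pytest.approx(0.3)
        assert curve.max_time == 5.0
        np.testing.assert_array_equal(curve.at_risk, [5, 4, 2])
        np.testing.assert_array_equal(curve.events, [1, 1, 1])

    def test_no_censoring_is_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5.0, 200)
        curve = km_estimate(t, np.ones(200, dtype=int))
        for q in (1.0, 3.0, 8.0):
            assert curve(q) == pytest.approx((t > q).mean(), abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            km_estimate([], [])
        with pytest.raises(ValueError):
            km_estimate([1.0, -2.0], [1, 1])

    def test_vectorised_call(self):
        curve = SurvivalCurve(times=[1.0, 2.0], survival=[0.5, 0.25])
        np.testing.assert_allclose(curve([0.5, 1.5, 5.0]), [1.0, 0.5, 0.25])


class TestLogrank:
    def test_separated_groups_rejected(self):
        rng = np.random.default_rng(1)
        t = np.concatenate([rng.exponential(1.0, 80),
                            rng.exponential(5.0, 80)])
        g = np.repeat(["a", "b"], 80)
        stat, p = logrank_test(g, t, np.ones(160, dtype=int))
        assert stat > 10
        assert p < 1e-3

    def test_identical_groups_not_rejected(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1.0, 400)
        g = np.repeat(["a", "b"], 200)
        _, p = logrank_test(g, t, np.ones(400, dtype=int))
        assert p > 0.01

    def test_one_group_raises(self):
        with pytest.raises(ValueError):
            logrank_test(["a", "a"], [1.0, 2.0], [1, 1])


class TestClusteredCox:
    def test_hand_oracle(self, hand_cohort):
        model = fit_cox(hand_cohort, covariates=["x"])
        assert model.coef_["x"] == pytest.approx(-np.log(2.0) / 2.0, abs=1e-4)

    def test_sklearn_contract(self):
        est = ClusteredCox(covariates=["age"], cluster_col="operator_id")
        assert est.get_params()["cluster_col"] == "operator_id"
        assert clone(est).get_params() == est.get_params()
        assert not hasattr(est, "coef_")

    def test_recovers_strong_effect(self, small_cohort):
        model = fit_cox(small_cohort, cluster_col="operator_id")
        # true log-HR for smoking is ln 2
        assert model.coef_["smoke"] == pytest.approx(np.log(2.0), abs=0.5)
        assert model.coef_["smoke"] > 0

    def test_robust_se_differs_from_naive(self, small_cohort):
        model = fit_cox(small_cohort, cluster_col="operator_id")
        assert model.se_robust_ is not None
        assert not np.allclose(model.se_robust_.to_numpy(),
                               model.se_naive_.to_numpy())
        unclustered = fit_cox(small_cohort)
        assert unclustered.se_robust_ is None

    def test_predict_survival_properties(self, small_cohort):
        model = fit_cox(small_cohort, cluster_col="operator_id")
        p30 = model.predict_survival(small_cohort, 30.0)
        p60 = model.predict_survival(small_cohort, 60.0)
        assert np.all((0 <= p30) & (p30 <= 1))
        assert np.all(p60 <= p30 + 1e-12)
        assert np.allclose(model.predict_survival(small_cohort, 0.0), 1.0)

    def test_predict_beyond_support_warns(self, small_cohort):
        model = fit_cox(small_cohort)
        far = small_cohort["time"].max() * 10
        with pytest.warns(RuntimeWarning):
            model.predict_survival(small_cohort, far)

    def test_baseline_survival_matches_prediction(self, small_cohort):
        model = fit_cox(small_cohort)
        base = model.baseline_survival()
        eta = model._linear_predictor(small_cohort)
        expected = base(30.0) ** np.exp(eta)
        np.testing.assert_allclose(model.predict_survival(small_cohort, 30.0),
                                   expected, atol=1e-12)

    def test_stratified_fit(self, small_cohort):
        model = ClusteredCox(strata_col="center_id").fit(small_cohort)
        for center in small_cohort["center_id"].unique():
            assert model.baseline_survival(center) is not None
        with pytest.raises(KeyError):
            model.baseline_survival("C99")

    def test_constant_covariate_raises(self, small_cohort):
        df = small_cohort.copy()
        df["flat"] = 1.0
        with pytest.raises(SingularDesignError):
            fit_cox(df, covariates=["age", "flat"])

    def test_summary_frame_layout(self, small_cohort):
        model = fit_cox(small_cohort, cluster_col="operator_id")
        frame = model.summary_frame()
        assert list(frame.columns) == ["term", "coef", "se", "robust_se",
                                       "HR", "ci_low", "ci_high", "p"]
        np.testing.assert_allclose(frame["HR"], np.exp(frame["coef"]))
        assert ((frame["ci_low"] <= frame["HR"])
                & (frame["HR"] <= frame["ci_high"])).all()


class TestGammaFrailtyCox:
    def test_theta_zero_reduces_to_cox(self, small_cohort):
        frail = fit_frailty(small_cohort, theta=0.0)
        cox = fit_cox(small_cohort)
        np.testing.assert_allclose(frail.coef_.to_numpy(),
                                   cox.coef_.to_numpy(), atol=1e-5)
        assert frail.theta_ == 0.0
        assert frail.frailty_pvalue_ == 1.0
        np.testing.assert_allclose(frail.frailties_.to_numpy(), 1.0,
                                   atol=1e-12)

    def test_frailties_mean_one(self, small_cohort):
        model = fit_frailty(small_cohort, theta=0.5)
        assert model.frailties_.mean() == pytest.approx(1.0, abs=1e-12)
        assert (model.frailties_ > 0).all()
        assert set(model.frailties_.index) == \
            set(small_cohort["operator_id"].unique())

    def test_theta_recovery(self, recovery_config):
        from frailcurve import generate_cohort
        df = generate_cohort(recovery_config)
        model = fit_frailty(df, covariates=["age", "smoke"])
        assert model.theta_ == pytest.approx(0.5, abs=0.2)
        assert model.coef_["smoke"] == pytest.approx(np.log(2.0), abs=0.25)
        assert model.coef_["age"] == pytest.approx(0.03, abs=0.015)
        assert model.frailty_pvalue_ < 0.01
        # posterior frailties should correlate with per-cluster event rates
        events = df.groupby("operator_id")["event"].mean()
        rho = np.corrcoef(model.frailties_.reindex(events.index), events)[0, 1]
        assert rho > 0.3

    def test_profile_likelihood_peaks_at_estimate(self, recovery_config):
        from frailcurve import generate_cohort
        df = generate_cohort(recovery_config)
        model = fit_frailty(df, covariates=["age", "smoke"])
        ll_hat = model.log_likelihood_
        for theta in (model.theta_ / 2, model.theta_ * 2):
            fixed = fit_frailty(df, covariates=["age", "smoke"], theta=theta)
            assert fixed.log_likelihood_ <= ll_hat + 1e-6
        assert model.null_log_likelihood_ <= ll_hat

    def test_prediction_uses_cluster_frailty(self, small_cohort):
        model = fit_frailty(small_cohort, theta=0.5)
        p = model.predict_survival(small_cohort, 30.0)
        assert np.all((0 <= p) & (p <= 1))
        # an unseen cluster falls back to the population frailty w = 1
        one = small_cohort.iloc[[0]].copy()
        one["operator_id"] = "ZZ-UNSEEN"
        p_unseen = model.predict_survival(one, 30.0)[0]
        eta = model._linear_predictor(one)[0]
        expected = model.baseline_survival()(30.0) ** np.exp(eta)
        assert p_unseen == pytest.approx(expected, abs=1e-12)

    def test_needs_two_clusters(self, small_cohort):
        df = small_cohort.copy()
        df["operator_id"] = "only-one"
        with pytest.raises(ValueError):
            fit_frailty(df)

    def test_summary_frame_carries_theta(self, small_cohort):
        model = fit_frailty(small_cohort, theta=0.3)
        frame = model.summary_frame()
        assert frame.attrs["theta"] == pytest.approx(0.3)
        assert "frailty_pvalue" in frame.attrs

    def test_sklearn_contract(self):
        est = GammaFrailtyCox(theta=0.2, cluster_col="operator_id")
        assert clone(est).get_params() == est.get_params()
        est.set_params(theta_max=5.0)
        assert est.theta_max == 5.0
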