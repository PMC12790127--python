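"""Survival estimation with provider heterogeneity.

Nonparametric pieces (Kaplan-Meier, log-rank) and the ordinary Cox model
with cluster-robust variance delegate to lifelines.  The shared gamma
frailty Cox model — an unobserved multiplicative hazard effect per operator,
gamma distributed with mean 1 and variance ``theta`` — is fit here by EM:

* E-step: posterior frailty mean ``w_j = (1/theta + D_j) / (1/theta + H_j)``
  with ``D_j`` the cluster's event count and
  ``H_j = sum_i Lambda0(t_i) exp(beta' x_i)`` its accumulated hazard;
* M-step: Cox partial-likelihood fit with the log-frailties as offsets,
  Breslow baseline per stratum;
* ``theta`` maximises the profile of the gamma-marginal log-likelihood, and
  the frailty test compares it to the no-frailty model with the usual 50:50
  chi-square(0)/chi-square(1) boundary mixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from . import _cox_core
from ._cox_core import ConvergenceError, SingularDesignError  # re-export
from .cohort import COVARIATE_COLUMNS


@dataclass
class SurvivalCurve:
    """A right-continuous survival step function.

    ``times`` are the distinct event times; ``survival`` the value just
    after each; ``at_risk``/``events`` the risk-set size and event count at
    each time.  ``max_time`` is the largest observed (event or censored)
    time, the end of the curve's support.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray = None
    events: np.ndarray = None
    max_time: float = None
    label: str | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.max_time is None:
            self.max_time = float(self.times[-1]) if len(self.times) else 0.0

    def __call__(self, t):
        """Survival probability at time(s) ``t`` (1 before the first event)."""
        pos = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        vals = np.concatenate([[1.0], self.survival])[pos]
        return float(vals) if np.ndim(t) == 0 else vals


def km_estimate(times, events, label: str | None = None) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    ev = tab[tab["observed"] > 0]
    etimes = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(etimes).to_numpy()
    return SurvivalCurve(times=etimes, survival=surv,
                         at_risk=ev["at_risk"].to_numpy(),
                         events=ev["observed"].to_numpy(),
                         max_time=float(times.max()), label=label)


def logrank_test(groups, times, events):
    """k-sample log-rank test; returns (chi-square statistic, p-value)."""
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(np.asarray(times, dtype=float), groups,
                                    np.asarray(events))
    return float(res.test_statistic), float(res.p_value)


def _design(df: pd.DataFrame, covariates, duration_col, event_col):
    X = df[list(covariates)].to_numpy(dtype=float)
    t = df[duration_col].to_numpy(dtype=float)
    d = df[event_col].to_numpy(dtype=int)
    if d.sum() < 1:
        raise ValueError("no events in the data")
    if np.any(t <= 0):
        raise ValueError("durations must be positive")
    if np.any(np.ptp(X, axis=0) == 0):
        bad = [c for c, r in zip(covariates, np.ptp(X, axis=0)) if r == 0]
        raise SingularDesignError(f"constant covariate(s): {bad}")
    return X, t, d


class ClusteredCox(BaseEstimator):
    """Cox proportional-hazards model with optional cluster-robust variance.

    A thin estimator over lifelines' ``CoxPHFitter`` (Efron ties) adding the
    Breslow baseline at zero covariates per stratum, naive and sandwich
    standard errors, and survival prediction at a horizon.

    Parameters
    ----------
    covariates : list of str, default all standard cohort covariates
    duration_col, event_col : column names for time and event indicator
    cluster_col : grouping column for the robust sandwich variance
    strata_col : optional stratification column for the baseline hazard
    """

    def __init__(self, covariates=None, duration_col="time", event_col="event",
                 cluster_col=None, strata_col=None):
        self.covariates = covariates
        self.duration_col = duration_col
        self.event_col = event_col
        self.cluster_col = cluster_col
        self.strata_col = strata_col

    def _covs(self, df):
        return list(self.covariates) if self.covariates is not None \
            else [c for c in COVARIATE_COLUMNS if c in df.columns]

    def fit(self, df: pd.DataFrame, y=None):
        covs = self._covs(df)
        X, t, d = _design(df, covs, self.duration_col, self.event_col)
        strata = df[self.strata_col].to_numpy() if self.strata_col else None

        cols = covs + [self.duration_col, self.event_col]
        if self.cluster_col:
            cols.append(self.cluster_col)
        if self.strata_col:
            cols.append(self.strata_col)
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[cols], duration_col=self.duration_col,
                    event_col=self.event_col,
                    cluster_col=self.cluster_col,
                    strata=self.strata_col,
                    fit_options={"precision": 1e-9, "max_steps": 500})
        self.lifelines_model_ = cph
        beta = cph.params_.reindex(covs).to_numpy()
        self.coef_ = pd.Series(beta, index=covs)
        # lifelines reports sandwich SEs when cluster_col is set; recover the
        # naive ones from the observed information at its estimate
        info_cov = _cox_core.newton_cox(X, t, d, strata=strata, beta0=beta,
                                        max_iter=1).cov
        self.se_naive_ = pd.Series(np.sqrt(np.diag(info_cov)), index=covs)
        self.se_robust_ = (cph.standard_errors_.reindex(covs)
                           if self.cluster_col else None)
        self.log_likelihood_ = float(cph.log_likelihood_)
        curves, cumhaz_at_obs = _cox_core.breslow_baseline(
            X, t, d, beta, strata=strata)
        self._store_baseline(curves, t, strata)
        self.cumhaz_at_obs_ = cumhaz_at_obs
        return self

    def _store_baseline(self, curves, t, strata):
        self.baseline_cumhaz_ = {}
        for lab, (etimes, cum, inc) in curves.items():
            if strata is None:
                mt = float(np.max(t))
            else:
                mt = float(np.max(t[np.asarray(strata) == lab]))
            self.baseline_cumhaz_[lab] = SurvivalCurve(
                times=etimes, survival=np.exp(-cum), max_time=mt, label=lab)

    # -- prediction ---------------------------------------------------------
    def _linear_predictor(self, df: pd.DataFrame):
        covs = self.coef_.index
        return df[list(covs)].to_numpy(dtype=float) @ self.coef_.to_numpy()

    def _log_frailty(self, df):
        return np.zeros(len(df))

    def baseline_survival(self, stratum=None) -> SurvivalCurve:
        if stratum not in self.baseline_cumhaz_:
            raise KeyError(f"unknown stratum {stratum!r}; "
                           f"have {list(self.baseline_cumhaz_)}")
        return self.baseline_cumhaz_[stratum]

    def predict_survival(self, df: pd.DataFrame, horizon: float) -> np.ndarray:
        """Per-subject survival probability ``S0(t)**exp(eta)`` at a horizon."""
        if horizon < 0:
            raise ValueError("horizon must be >= 0")
        eta = self._linear_predictor(df) + self._log_frailty(df)
        out = np.empty(len(df))
        strata_vals = (df[self.strata_col].to_numpy() if self.strata_col
                       else np.full(len(df), None))
        for lab in set(strata_vals):
            curve = self.baseline_survival(lab)
            idx = np.flatnonzero(strata_vals == lab) if lab is not None \
                else np.arange(len(df))
            t_eval = horizon
            if horizon > curve.max_time:
                warnings.warn("horizon beyond baseline support; using the "
                              "value at the last observed time", RuntimeWarning,
                              stacklevel=2)
                t_eval = curve.max_time
            out[idx] = curve(t_eval) ** np.exp(eta[idx])
        return out

    def summary_frame(self) -> pd.DataFrame:
        """Model summary in the (term, coef, se, robust se, HR, CI, p) layout."""
        se = (self.se_robust_ if self.se_robust_ is not None
              else self.se_naive_)
        z = self.coef_ / se
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({
            "term": self.coef_.index,
            "coef": self.coef_.to_numpy(),
            "se": self.se_naive_.to_numpy(),
            "robust_se": (self.se_robust_.to_numpy()
                          if self.se_robust_ is not None else np.nan),
            "HR": np.exp(self.coef_.to_numpy()),
            "ci_low": np.exp(self.coef_.to_numpy() - 1.96 * se.to_numpy()),
            "ci_high": np.exp(self.coef_.to_numpy() + 1.96 * se.to_numpy()),
            "p": p,
        }).reset_index(drop=True)


class GammaFrailtyCox(BaseEstimator):
    """Cox model with a shared gamma frailty per cluster, fit by EM.

    Fitted attributes: ``coef_``, ``se_``, ``theta_`` (frailty variance),
    ``frailties_`` (posterior means, normalised to mean exactly 1 with the
    baseline rescaled to compensate), ``frailty_pvalue_`` (boundary-mixture
    likelihood-ratio test of ``theta = 0``), ``baseline_cumhaz_`` per
    stratum, ``log_likelihood_`` (gamma-marginal, Breslow plug-in).

    Set ``theta`` to a number to fix the frailty variance instead of
    estimating it (``theta=0`` reduces exactly to the ordinary Cox fit).
    """

    def __init__(self, covariates=None, duration_col="time", event_col="event",
                 cluster_col="operator_id", strata_col=None, theta=None,
                 theta_max=10.0, tol=1e-8, max_em_iter=200):
        self.covariates = covariates
        self.duration_col = duration_col
        self.event_col = event_col
        self.cluster_col = cluster_col
        self.strata_col = strata_col
        self.theta = theta
        self.theta_max = theta_max
        self.tol = tol
        self.max_em_iter = max_em_iter

    def _covs(self, df):
        return list(self.covariates) if self.covariates is not None \
            else [c for c in COVARIATE_COLUMNS if c in df.columns]

    # gamma-marginal log-likelihood with Breslow plug-in baseline
    @staticmethod
    def _marginal_loglik(theta, eta, event, log_inc_per_event, D, H):
        ll = float(np.sum(log_inc_per_event) + np.sum(eta[event.astype(bool)]))
        if theta <= 0:
            return ll - float(np.sum(H))
        a = 1.0 / theta
        ll += float(np.sum(special.gammaln(a + D) - special.gammaln(a)
                           + a * np.log(a) - (a + D) * np.log(a + H)))
        return ll

    def _em_at_theta(self, theta, state):
        X, t, d, strata, cl_idx, D, n_cl = (state[k] for k in
                                            ("X", "t", "d", "strata",
                                             "cl_idx", "D", "n_cl"))
        beta = state["warm_beta"].copy()
        w = state["warm_w"].copy() if theta > 0 else np.ones(n_cl)
        prev_ll = -np.inf
        fit = None
        for it in range(1, self.max_em_iter + 1):
            offset = np.log(w)[cl_idx]
            fit = _cox_core.newton_cox(X, t, d, offset=offset, strata=strata,
                                       beta0=beta, tol=1e-10, max_iter=40)
            beta = fit.beta
            curves, cumhaz = _cox_core.breslow_baseline(
                X, t, d, beta, offset=offset, strata=strata)
            eta = X @ beta
            # cumhaz above includes the offsets through the risk sets only;
            # H_j excludes the frailty itself
            H = np.bincount(cl_idx, weights=cumhaz * np.exp(eta),
                            minlength=n_cl)
            log_inc = self._log_increment_per_event(curves, t, d, strata)
            ll = self._marginal_loglik(theta, eta, d, log_inc, D, H)
            if theta <= 0:
                break
            w = (1.0 / theta + D) / (1.0 / theta + H)
            if abs(ll - prev_ll) < self.tol * (abs(ll) + self.tol):
                break
            prev_ll = ll
        state["warm_beta"] = beta.copy()
        if theta > 0:
            state["warm_w"] = w.copy()
        return {"theta": theta, "beta": beta, "w": w, "curves": curves,
                "cumhaz": cumhaz, "loglik": ll, "cov": fit.cov,
                "offset": np.log(w)[cl_idx], "n_iter": it}

    @staticmethod
    def _log_increment_per_event(curves, t, d, strata):
        """log Breslow hazard increment share for each event, pooled."""
        out = []
        labels = [None] if strata is None else list(np.unique(np.asarray(strata)))
        for lab in labels:
            idx = np.arange(len(t)) if lab is None else \
                np.flatnonzero(np.asarray(strata) == lab)
            etimes, _, inc = curves[lab]
            ev = idx[d[idx].astype(bool)]
            pos = np.searchsorted(etimes, t[ev])
            # multiplicity of each event time within the stratum
            mult = np.bincount(pos, minlength=len(etimes))
            out.append(np.log(inc[pos] / mult[pos]))
        return np.concatenate(out) if out else np.array([])

    def fit(self, df: pd.DataFrame, y=None):
        covs = self._covs(df)
        X, t, d = _design(df, covs, self.duration_col, self.event_col)
        strata = df[self.strata_col].to_numpy() if self.strata_col else None
        clusters = df[self.cluster_col].to_numpy()
        labels, cl_idx = np.unique(clusters, return_inverse=True)
        if len(labels) < 2:
            raise ValueError("frailty model needs at least two clusters")
        D = np.bincount(cl_idx, weights=d.astype(float), minlength=len(labels))
        state = {"X": X, "t": t, "d": d, "strata": strata, "cl_idx": cl_idx,
                 "D": D, "n_cl": len(labels),
                 "warm_beta": np.zeros(X.shape[1]), "warm_w": np.ones(len(labels))}

        null = self._em_at_theta(0.0, state)
        if self.theta is not None and self.theta == 0:
            best = null
        elif self.theta is not None:
            best = self._em_at_theta(float(self.theta), state)
        else:
            cache = {}
            def neg_profile(theta):
                if theta not in cache:
                    cache[theta] = self._em_at_theta(theta, state)
                return -cache[theta]["loglik"]
            # cheap probes: if the profile is below the null everywhere on a
            # coarse grid, the MLE sits on the boundary theta = 0
            probes = [0.002, 0.01, 0.05, 0.2, 1.0]
            probe_ll = [-neg_profile(p) for p in probes]
            if max(probe_ll) <= null["loglik"]:
                best = null
            else:
                res = optimize.minimize_scalar(
                    neg_profile, bounds=(1e-4, self.theta_max),
                    method="bounded", options={"xatol": 1e-4})
                cand = cache[res.x] if res.x in cache else \
                    self._em_at_theta(float(res.x), state)
                best = cand if cand["loglik"] > null["loglik"] else null

        # normalise frailties to mean 1; rescale baseline so w*Lambda0 is
        # unchanged (pure reparameterisation of the reported quantities)
        w = best["w"]
        scale = float(np.mean(w))
        w = w / scale
        curves = {lab: (et, cum * scale, inc * scale)
                  for lab, (et, cum, inc) in best["curves"].items()}
        cumhaz = best["cumhaz"] * scale

        self.coef_ = pd.Series(best["beta"], index=covs)
        self.se_ = pd.Series(np.sqrt(np.diag(best["cov"])), index=covs)
        self.theta_ = float(best["theta"])
        self.frailties_ = pd.Series(w, index=labels)
        self.log_likelihood_ = float(best["loglik"])
        self.null_log_likelihood_ = float(null["loglik"])
        self.cumhaz_at_obs_ = cumhaz
        self.n_em_iter_ = best["n_iter"]
        self._cluster_labels_ = labels
        self.baseline_cumhaz_ = {}
        for lab, (etimes, cum, _) in curves.items():
            mt = float(np.max(t)) if strata is None else \
                float(np.max(t[np.asarray(strata) == lab]))
            self.baseline_cumhaz_[lab] = SurvivalCurve(
                times=etimes, survival=np.exp(-cum), max_time=mt, label=lab)

        if self.theta_ <= 0:
            self.frailty_pvalue_ = 1.0
        else:
            lr = max(0.0, 2.0 * (self.log_likelihood_ - self.null_log_likelihood_))
            self.frailty_pvalue_ = float(0.5 * stats.chi2.sf(lr, 1)) if lr > 0 else 1.0
        return self

    # -- prediction (shared surface with ClusteredCox) ----------------------
    baseline_survival = ClusteredCox.baseline_survival
    predict_survival = ClusteredCox.predict_survival
    _linear_predictor = ClusteredCox._linear_predictor

    def _log_frailty(self, df):
        w = self.frailties_.reindex(df[self.cluster_col]).to_numpy()
        w = np.where(np.isnan(w), 1.0, w)  # unseen cluster: population frailty
        return np.log(w)

    def summary_frame(self) -> pd.DataFrame:
        z = self.coef_ / self.se_
        p = 2 * stats.norm.sf(np.abs(z))
        frame = pd.DataFrame({
            "term": self.coef_.index,
            "coef": self.coef_.to_numpy(),
            "se": self.se_.to_numpy(),
            "robust_se": np.nan,
            "HR": np.exp(self.coef_.to_numpy()),
            "ci_low": np.exp(self.coef_.to_numpy() - 1.96 * self.se_.to_numpy()),
            "ci_high": np.exp(self.coef_.to_numpy() + 1.96 * self.se_.to_numpy()),
            "p": p,
        })
        frame.attrs["theta"] = self.theta_
        frame.attrs["frailty_pvalue"] = self.frailty_pvalue_
        return frame


def fit_cox(df, covariates=None, cluster_col=None, strata_col=None,
            duration_col="time", event_col="event") -> ClusteredCox:
    """Fit a (cluster-robust, optionally stratified) Cox model."""
    return ClusteredCox(covariates=covariates, duration_col=duration_col,
                        event_col=event_col, cluster_col=cluster_col,
                        strata_col=strata_col).fit(df)


def fit_frailty(df, covariates=None, cluster_col="operator_id",
                strata_col=None, duration_col="time", event_col="event",
                theta=None) -> GammaFrailtyCox:
    """Fit a shared gamma-frailty Cox model (EM, profile theta)."""
    return GammaFrailtyCox(covariates=covariates, duration_col=duration_col,
                           event_col=event_col, cluster_col=cluster_col,
                           strata_col=strata_col, theta=theta).fit(df)


def baseline_survival(fit, stratum=None) -> SurvivalCurve:
    return fit.baseline_survival(stratum)


def predict_survival(fit, df, horizon: float) -> np.ndarray:
    return fit.predict_survival(df, horizon)


__all__ = [
    "SurvivalCurve", "ClusteredCox", "GammaFrailtyCox", "km_estimate",
    "logrank_test", "fit_cox", "fit_frailty", "baseline_survival",
    "predict_survival", "SingularDesignError", "ConvergenceError",
]
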