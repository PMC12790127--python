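"""Internal Cox partial-likelihood machinery.

A compact Newton solver for the Cox proportional-hazards model with
per-subject *offsets* (fixed additions to the linear predictor) and optional
strata.  Offsets are what the gamma-frailty EM needs in its M-step — the
posterior log-frailties enter the linear predictor with coefficient one —
and general-purpose Cox packages do not expose them, so this lives here.
The public model surface is in :mod:`frailcurve.survival`.

Ties: the Efron approximation is used for the partial likelihood.  When all
event times are distinct (the generic case for continuous simulated times)
the computation collapses to a fully vectorised cumulative-sum form; tied
event times fall back to a per-tie loop.  Baseline cumulative-hazard
increments are Breslow (``d_k / sum of risk scores``) in all cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CoxCoreFit:
    """Raw output of the internal Newton solver."""

    beta: np.ndarray          # (p,) coefficients
    cov: np.ndarray           # (p, p) inverse observed information
    loglik: float             # Efron partial log-likelihood at beta
    n_iter: int
    converged: bool


class SingularDesignError(ValueError):
    """Design matrix is singular (e.g. a constant covariate)."""


class ConvergenceError(RuntimeError):
    """Newton iterations failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def _stratum_indices(strata: np.ndarray | None, n: int) -> list[np.ndarray]:
    if strata is None:
        return [np.arange(n)]
    strata = np.asarray(strata)
    return [np.flatnonzero(strata == s) for s in np.unique(strata)]


def _loglik_grad_hess(X, time, event, eta, want_derivs=True):
    """Efron partial log-likelihood and derivatives for one stratum.

    Inputs must be sorted by ascending time.  ``eta`` is the full linear
    predictor (X @ beta + offset).
    """
    n, p = X.shape
    r = np.exp(eta)
    rx = r[:, None] * X

    # group rows by unique time (ties share a risk set)
    utimes, first_idx, counts = np.unique(time, return_index=True, return_counts=True)
    G = len(utimes)
    # per-group sums of risk scores and score-weighted covariates
    g_r = np.add.reduceat(r, first_idx)
    g_rx = np.add.reduceat(rx, first_idx, axis=0)
    # reverse cumulative sums: risk-set totals at each unique time
    S0 = np.cumsum(g_r[::-1])[::-1]
    S1 = np.cumsum(g_rx[::-1], axis=0)[::-1]

    # per-group event counts and event-only sums
    ev = event.astype(bool)
    d_g = np.add.reduceat(ev.astype(np.int64), first_idx)
    e_r = np.add.reduceat(np.where(ev, r, 0.0), first_idx)
    e_rx = np.add.reduceat(np.where(ev[:, None], rx, 0.0), first_idx, axis=0)
    e_x = np.add.reduceat(np.where(ev[:, None], X, 0.0), first_idx, axis=0)
    e_eta = np.add.reduceat(np.where(ev, eta, 0.0), first_idx)

    has_event = d_g > 0
    single = has_event & (d_g == 1)
    multi = has_event & (d_g > 1)

    ll = float(np.sum(e_eta[has_event]))
    # untied events: Efron == Breslow
    ll -= float(np.sum(np.log(S0[single])))

    grad = None
    hess = None
    if want_derivs:
        S2 = None
        # second moments only when derivatives requested
        rxx = rx[:, :, None] * X[:, None, :]
        g_rxx = np.add.reduceat(rxx, first_idx, axis=0)
        S2 = np.cumsum(g_rxx[::-1], axis=0)[::-1]
        e_rxx = np.add.reduceat(np.where(ev[:, None, None], rxx, 0.0), first_idx, axis=0)

        grad = e_x[has_event].sum(axis=0)
        hess = np.zeros((p, p))
        if single.any():
            u = S1[single] / S0[single][:, None]
            grad -= u.sum(axis=0)
            hess += np.einsum("kij,k->ij", S2[single], 1.0 / S0[single])
            hess -= np.einsum("ki,kj->ij", u, u)
        for k in np.flatnonzero(multi):
            d = int(d_g[k])
            frac = np.arange(d) / d
            phi = S0[k] - frac * e_r[k]                       # (d,)
            num1 = S1[k][None, :] - frac[:, None] * e_rx[k]    # (d, p)
            num2 = S2[k][None, :, :] - frac[:, None, None] * e_rxx[k]
            ll -= float(np.sum(np.log(phi)))
            v = num1 / phi[:, None]
            grad -= v.sum(axis=0)
            hess += np.einsum("lij,l->ij", num2, 1.0 / phi)
            hess -= np.einsum("li,lj->ij", v, v)
    else:
        for k in np.flatnonzero(multi):
            d = int(d_g[k])
            frac = np.arange(d) / d
            ll -= float(np.sum(np.log(S0[k] - frac * e_r[k])))

    return ll, grad, hess


def partial_loglik(X, time, event, beta, offset=None, strata=None) -> float:
    """Efron partial log-likelihood at ``beta`` (no derivatives)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if offset is None:
        offset = np.zeros(n)
    eta = X @ np.asarray(beta, dtype=float) + offset
    total = 0.0
    for idx in _stratum_indices(strata, n):
        order = np.argsort(time[idx], kind="stable")
        sub = idx[order]
        ll, _, _ = _loglik_grad_hess(X[sub], time[sub], event[sub], eta[sub],
                                     want_derivs=False)
        total += ll
    return total


def newton_cox(X, time, event, offset=None, strata=None, beta0=None,
               tol: float = 1e-9, max_iter: int = 50) -> CoxCoreFit:
    """Maximise the Efron partial likelihood by Newton-Raphson.

    Step-halving guards against overshoot; a singular information matrix
    raises :class:`SingularDesignError`.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    n, p = X.shape
    if event.sum() < 1:
        raise ValueError("at least one event is required")
    if np.any(np.ptp(X, axis=0) == 0):
        raise SingularDesignError("constant covariate in the design matrix")
    if offset is None:
        offset = np.zeros(n)
    offset = np.asarray(offset, dtype=float)

    strata_idx = _stratum_indices(strata, n)
    # pre-sort each stratum once
    sorted_parts = []
    for idx in strata_idx:
        order = np.argsort(time[idx], kind="stable")
        sub = idx[order]
        sorted_parts.append((X[sub], time[sub], event[sub], offset[sub]))

    def evaluate(beta, want_derivs=True):
        ll = 0.0
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        for Xs, ts, es, os_ in sorted_parts:
            eta = Xs @ beta + os_
            l, g, h = _loglik_grad_hess(Xs, ts, es, eta, want_derivs)
            ll += l
            if want_derivs:
                grad += g
                hess += h
        return ll, grad, hess

    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll, grad, hess = evaluate(beta)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError(f"singular information matrix: {exc}") from exc
        # step-halving
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = evaluate(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        trace.append(ll_new)
        done = abs(ll_new - ll) < tol * (abs(ll) + tol)
        ll, grad, hess = ll_new, grad_new, hess_new
        if done:
            converged = True
            break
    if not converged and max_iter > 1:
        # monotone likelihood (separation) shows up as a huge |beta|
        if np.max(np.abs(beta)) > 50:
            import warnings

            warnings.warn("possible monotone likelihood; coefficients capped "
                          "at the last iterate", RuntimeWarning, stacklevel=2)
        else:
            raise ConvergenceError(
                f"Newton did not converge in {max_iter} iterations", trace)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(f"singular information matrix: {exc}") from exc
    return CoxCoreFit(beta=beta, cov=cov, loglik=ll, n_iter=it, converged=converged)


def breslow_baseline(X, time, event, beta, offset=None, strata=None):
    """Breslow baseline cumulative hazard per stratum.

    Returns ``(curves, cumhaz_at_obs)`` where ``curves`` maps stratum label
    to ``(event_times, cumulative_hazard, increments)`` arrays and
    ``cumhaz_at_obs`` is the baseline cumulative hazard evaluated at each
    subject's own observed time (in input row order).
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    n = X.shape[0]
    if offset is None:
        offset = np.zeros(n)
    eta = X @ np.asarray(beta, dtype=float) + np.asarray(offset, dtype=float)
    r = np.exp(eta)

    labels = [None] if strata is None else list(np.unique(np.asarray(strata)))
    curves = {}
    cumhaz_at_obs = np.zeros(n)
    for lab in labels:
        idx = np.arange(n) if lab is None else np.flatnonzero(np.asarray(strata) == lab)
        ts, es, rs = time[idx], event[idx], r[idx]
        order = np.argsort(ts, kind="stable")
        ts, es, rs = ts[order], es[order], rs[order]
        utimes, first_idx = np.unique(ts, return_index=True)
        g_r = np.add.reduceat(rs, first_idx)
        S0 = np.cumsum(g_r[::-1])[::-1]
        d_g = np.add.reduceat(es.astype(np.int64), first_idx)
        ev_mask = d_g > 0
        inc = d_g[ev_mask] / S0[ev_mask]
        etimes = utimes[ev_mask]
        cum = np.cumsum(inc)
        curves[lab] = (etimes, cum, inc)
        # evaluate at each subject's observed time
        pos = np.searchsorted(etimes, time[idx], side="right")
        cumhaz_at_obs[idx] = np.concatenate([[0.0], cum])[pos]
    return curves, cumhaz_at_obs
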