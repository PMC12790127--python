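"""The learning-curve framework.

Given a fitted survival backend (Cox, frailty Cox, tau-truncated RMST
frailty Cox, or random survival forest) the pipeline builds the multilevel
learning-curve quantities:

* ``p0`` — per-subject predicted survival at the evaluation horizon from
  the backend *without* any case-order term: the asymptotic steady-state
  success probability;
* ``p1`` — physician-level predictions: the backend is refit with the
  ordered procedure variable, a parametric shape is fit to the resulting
  predictions against operator case order (pooled across operators at equal
  order), and ``p1_i`` is the fitted shape at subject ``i``'s order;
* ``p2`` — center-level predictions: the same shape family refit to ``p1``
  against the center's cumulative case volume;
* the survival-time update ``tnew_i = (p2_i / p0_i) * time_i``, after which
  the backend is refit once on the updated times to produce the final
  success probabilities that are binned against volume and summarised by
  the MSE family.

MSE metrics (all mean squared errors): ``mse1`` between the marginal
success rates observed in the data (a Kaplan-Meier estimate at the horizon
within each volume bin) and the fitted curve at the bin centres; ``mse2``
between ``p0`` and the fitted shape values; ``mse2_a`` between ``p0`` and
``p1``; ``mse2_b`` between ``p1`` and ``p2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import COVARIATE_COLUMNS
from .rmst import RMSTFrailtyCox
from .rsf import RandomSurvivalForestBackend
from .shapes import ShapeSpec, bin_observed, fit_shape, shape_value
from .survival import ClusteredCox, GammaFrailtyCox

BACKENDS = ("cox", "frailty", "rmst_frailty", "rsf")


@dataclass
class MSEReport:
    mse1: float
    mse2: float
    mse2_a: float
    mse2_b: float

    def as_dict(self):
        return {"mse1": self.mse1, "mse2": self.mse2,
                "mse2_a": self.mse2_a, "mse2_b": self.mse2_b}


@dataclass
class LCResult:
    """All per-subject learning-curve quantities for one backend and shape."""

    backend: str
    kind: str
    horizon: float
    case_order: np.ndarray
    center_volume: np.ndarray
    p0: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    tnew: np.ndarray
    p_updated: np.ndarray
    shape_fits: dict = field(default_factory=dict)  # level -> ShapeSpec
    binned: list = field(default_factory=list)      # (bin centre, mean predicted)
    observed_success: list = field(default_factory=list)  # (bin centre, KM at horizon)
    mse: MSEReport | None = None


def _mse(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch between compared vectors")
    return float(np.mean((a - b) ** 2))


def mse_report(binned, fitted_at_centers, p0, p1, p2, shape_values) -> MSEReport:
    """The four-MSE summary of one learning-curve run."""
    observed = [v for _, v in binned]
    return MSEReport(
        mse1=_mse(observed, fitted_at_centers),
        mse2=_mse(p0, shape_values),
        mse2_a=_mse(p0, p1),
        mse2_b=_mse(p1, p2),
    )


def _make_backend(backend: str, covariates, seed: int, tau, rsf_trees: int):
    if backend == "cox":
        return ClusteredCox(covariates=covariates, cluster_col="operator_id")
    if backend == "frailty":
        return GammaFrailtyCox(covariates=covariates, cluster_col="operator_id")
    if backend == "rmst_frailty":
        return RMSTFrailtyCox(covariates=covariates, cluster_col="operator_id",
                              tau=tau)
    if backend == "rsf":
        return RandomSurvivalForestBackend(covariates=covariates, seed=seed,
                                           n_trees=rsf_trees)
    raise ValueError(f"unknown backend {backend!r}; expected one of {BACKENDS}")


def _predictions(backend, df, covariates, horizon, seed, tau, rsf_trees):
    model = _make_backend(backend, covariates, seed, tau, rsf_trees)
    model.fit(df)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return model.predict_survival(df, horizon)


def binned_marginal_success(df: pd.DataFrame, horizon: float,
                            bin_width: int = 5) -> list:
    """Marginal success rate observed in the data per volume bin.

    For each case-order bin, a Kaplan-Meier estimate of survival at the
    horizon using only the subjects in that bin (censoring-consistent, so it
    remains a success *rate*, not a raw event proportion).  Returns
    ``(bin centre, rate)`` pairs; empty bins are omitted.
    """
    from .survival import km_estimate

    order = df["case_order"].to_numpy(dtype=float)
    idx = np.floor((order - 1.0) / bin_width).astype(int)
    points = []
    for k in np.unique(idx):
        sub = df.iloc[np.flatnonzero(idx == k)]
        center = 1.0 + k * bin_width + (bin_width - 1) / 2.0
        curve = km_estimate(sub["time"], sub["event"])
        points.append((float(center), float(curve(horizon))))
    return points


def center_cumulative_volume(df: pd.DataFrame) -> np.ndarray:
    """Cumulative case count within each center, in procedure-date order.

    Procedures within a center are ordered by case order (the per-operator
    date order), breaking ties by operator id, which interleaves the
    operators' sequences the way concurrent practice would.
    """
    vol = np.empty(len(df), dtype=float)
    for _, idx in df.groupby("center_id").indices.items():
        sub = df.iloc[idx]
        rank = np.lexsort((sub["operator_id"].to_numpy(),
                           sub["case_order"].to_numpy()))
        v = np.empty(len(idx), dtype=float)
        v[rank] = np.arange(1, len(idx) + 1)
        vol[idx] = v
    return vol


def run_lc_pipeline(df: pd.DataFrame, backend: str = "cox",
                    kind: str = "logarithmic", horizon: float = 30.0,
                    bin_width: int = 5, covariates=None, seed: int = 0,
                    tau=None, rsf_trees: int = 200) -> LCResult:
    """Run the full multilevel learning-curve pipeline on one cohort."""
    covariates = (list(covariates) if covariates is not None
                  else [c for c in COVARIATE_COLUMNS if c in df.columns])
    order = df["case_order"].to_numpy(dtype=float)
    center_vol = center_cumulative_volume(df)
    time = df["time"].to_numpy(dtype=float)

    # (a) steady-state predictions, no order term
    p0 = _predictions(backend, df, covariates, horizon, seed, tau, rsf_trees)

    # (b) physician level: refit with the ordered procedure variable
    df_order = df.copy()
    df_order["case_order_cov"] = order
    q = _predictions(backend, df_order, covariates + ["case_order_cov"],
                     horizon, seed, tau, rsf_trees)
    phys_spec, _ = fit_shape(order, q, kind, random_state=seed)
    p1 = shape_value(phys_spec, order)

    # (c) center level: same family at center cumulative volume
    center_spec, _ = fit_shape(center_vol, p1, kind, random_state=seed)
    p2 = shape_value(center_spec, center_vol)

    # (d) survival-time update and a single refit pass: the updated times
    # become the new time variable in the order-including model, producing
    # the final per-subject success probabilities
    p0_safe = np.clip(p0, 1e-6, None)
    tnew = (p2 / p0_safe) * time
    tnew = np.maximum(tnew, 1e-9)
    df_new = df_order.copy()
    df_new["time"] = tnew
    p_updated = _predictions(backend, df_new,
                             covariates + ["case_order_cov"], horizon, seed,
                             tau, rsf_trees)

    # (e) final curve, binned points and the MSE family; mse1 compares the
    # fitted curve with the marginal success rates observed in the data
    final_spec, _ = fit_shape(order, p_updated, kind, random_state=seed)
    binned = bin_observed(order, p_updated, bin_width)
    observed = binned_marginal_success(df, horizon, bin_width)
    centers = np.array([c for c, _ in observed])
    fitted_at_centers = shape_value(final_spec, centers)
    shape_vals = shape_value(final_spec, order)
    report = mse_report(observed, fitted_at_centers, p0, p1, p2, shape_vals)

    return LCResult(backend=backend, kind=kind, horizon=horizon,
                    case_order=order, center_volume=center_vol,
                    p0=p0, p1=p1, p2=p2, tnew=tnew, p_updated=p_updated,
                    shape_fits={"physician": phys_spec, "center": center_spec,
                                "final": final_spec},
                    binned=binned, observed_success=observed, mse=report)


def update_times(p0, p2, time) -> np.ndarray:
    """The survival-time update rule ``tnew = (p2 / p0) * time``."""
    p0 = np.asarray(p0, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    time = np.asarray(time, dtype=float)
    return (p2 / p0) * time


__all__ = ["BACKENDS", "MSEReport", "LCResult", "mse_report",
           "run_lc_pipeline", "update_times", "center_cumulative_volume",
           "ShapeSpec"]
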