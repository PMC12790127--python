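"""Cohort CSV schema, config files, table layouts and plot-data export.

The cohort travels as a CSV with the fixed column order documented in
:data:`frailcurve.cohort.COHORT_COLUMNS`; the generating seed and config go
into a JSON sidecar (``<path>.meta.json``).  Study tables are plain CSV in
three layouts: the scenario grid (``table6``), the per-scenario MSE summary
(``table7``) and the multilevel probability summary (``table8``); missing
cells are written as the explicit token ``NA``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import COHORT_COLUMNS, ScenarioConfig
from .shapes import ShapeSpec, shape_value

NA_TOKEN = "NA"


def write_cohort(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.10g",
              columns=[c for c in COHORT_COLUMNS if c in df.columns])
    meta = dict(metadata or {})
    meta.setdefault("config", df.attrs.get("config"))
    meta.setdefault("censoring_rate_param", df.attrs.get("censoring_rate_param"))
    Path(str(path) + ".meta.json").write_text(
        json.dumps(meta, indent=2, default=str))


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("operator_id", "center_id", "case_order",
                           "time", "event") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks required columns: {missing}")
    meta_path = Path(str(path) + ".meta.json")
    if meta_path.exists():
        df.attrs["metadata"] = json.loads(meta_path.read_text())
    return df


class ConfigError(ValueError):
    pass


def load_study_config(path) -> dict:
    """Load and validate a study YAML/JSON config.

    Recognised keys: ``backends`` (list), ``n_reps`` (int or mapping),
    ``master_seed`` (int), ``scenarios`` (list of ids 1-16), ``rsf_trees``,
    and scenario overrides (``n_centers``, ``cases_per_physician``,
    ``theta_true``, ``baseline_rate``).
    """
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("study config must be a mapping")
    allowed = {"backends", "n_reps", "master_seed", "scenarios", "rsf_trees",
               "n_centers", "cases_per_physician", "theta_true",
               "baseline_rate"}
    unknown = set(cfg) - allowed
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    from .learning import BACKENDS
    for b in cfg.get("backends", []):
        if b not in BACKENDS:
            raise ConfigError(f"unknown backend {b!r}")
    scen = cfg.get("scenarios")
    if scen is not None and not all(isinstance(s, int) and 1 <= s <= 16
                                    for s in scen):
        raise ConfigError("scenarios must be integers in 1..16")
    if "master_seed" in cfg and not isinstance(cfg["master_seed"], int):
        raise ConfigError("master_seed must be an integer")
    return cfg


# -- study table layouts ----------------------------------------------------

def table6_frame(grid) -> pd.DataFrame:
    rows = [{
        "scenario": c.scenario_id,
        "physicians_per_center": c.physicians_per_center,
        "censoring": f"{c.censoring_target:.0%}",
        "shape": c.true_shape.kind if c.true_shape else "none",
    } for c in grid]
    return pd.DataFrame(rows, columns=["scenario", "physicians_per_center",
                                       "censoring", "shape"])


def table7_frame(results) -> pd.DataFrame:
    rows = []
    for res in results:
        row = {"scenario": res.scenario_id}
        for backend, metrics in res.mse.items():
            for key in ("mse1", "mse2", "mse2_a", "mse2_b"):
                row[f"{backend}_{key}"] = metrics.get(key, np.nan)
            row[f"{backend}_failures"] = res.failures.get(backend, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def table8_frame(results) -> pd.DataFrame:
    rows = []
    for res in results:
        row = {"scenario": res.scenario_id}
        for backend, levels in res.levels.items():
            for key, val in levels.items():
                row[f"{backend}_{key}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def model_summary_frame(fit) -> pd.DataFrame:
    return fit.summary_frame()


_LAYOUTS = {"table6": table6_frame, "table7": table7_frame,
            "table8": table8_frame, "model_summary": model_summary_frame}


def write_table(result, layout: str, path) -> None:
    """Write a result in one of the fixed table layouts (deterministic
    column order, ``NA`` for missing cells)."""
    if layout not in _LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; expected {list(_LAYOUTS)}")
    frame = _LAYOUTS[layout](result)
    frame.to_csv(path, index=False, na_rep=NA_TOKEN, float_format="%.6g")


def plot_lc_data(lc_result, path) -> pd.DataFrame:
    """Long-format learning-curve plot data: (volume, series, value).

    Series: the binned ``observed`` means, the ``fitted`` final shape at the
    bin centres, and per-subject ``p0``/``p1``/``p2`` against case order.
    """
    rows = []
    for center, mean in lc_result.binned:
        rows.append({"volume": center, "series": "observed", "value": mean})
        rows.append({"volume": center, "series": "fitted",
                     "value": shape_value(lc_result.shape_fits["final"], center)})
    for name in ("p0", "p1", "p2"):
        vals = getattr(lc_result, name)
        for v, p in zip(lc_result.case_order, vals):
            rows.append({"volume": float(v), "series": name, "value": float(p)})
    frame = pd.DataFrame(rows, columns=["volume", "series", "value"])
    if path is not None:
        frame.to_csv(path, index=False, na_rep=NA_TOKEN, float_format="%.6g")
    return frame


def render_lc_plot(lc_result, path) -> None:
    """Basic built-in renderer for one learning curve (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if lc_result.binned:
        xs, ys = zip(*lc_result.binned)
        ax.scatter(xs, ys, label="observed (binned)", color="k", zorder=3)
        grid = np.linspace(1, max(xs), 200)
        ax.plot(grid, shape_value(lc_result.shape_fits["final"], grid),
                label=f"{lc_result.kind} fit")
    ax.set_xlabel("case volume")
    ax.set_ylabel("predicted probability of success")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


__all__ = ["write_cohort", "read_cohort", "load_study_config", "ConfigError",
           "write_table", "table6_frame", "table7_frame", "table8_frame",
           "plot_lc_data", "render_lc_plot", "NA_TOKEN"]
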