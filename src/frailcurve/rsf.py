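"""Random survival forest backend.

A thin, reproducible contract around scikit-survival's
``RandomSurvivalForest`` so the learning-curve pipeline can use a
model-free survival estimator interchangeably with the Cox-family models.
The forest algorithm itself is delegated; this module only fixes the
prediction contract (per-subject survival probability at a horizon,
out-of-bag where possible) and the hyperparameter bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import COVARIATE_COLUMNS


class CapabilityError(RuntimeError):
    """The forest backend is unavailable in this installation."""


def _eval_step(fn, t: float) -> float:
    """Evaluate a scikit-survival step function, clamping to its support
    (survival is 1 before the first event time)."""
    x = fn.x
    if t < x[0]:
        return 1.0
    return float(fn(min(t, x[-1])))


@dataclass(frozen=True)
class RsfConfig:
    """Forest hyperparameters; recorded in output metadata."""

    n_trees: int = 500
    min_node_size: int = 15
    mtry: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


class RandomSurvivalForestBackend(BaseEstimator):
    """Random survival forest with the shared survival-prediction surface.

    Parameters mirror :class:`RsfConfig`; ``oob=True`` returns out-of-bag
    ensemble predictions on the training data where the scikit-learn
    bootstrap bookkeeping is available, falling back (with a warning) to
    full-ensemble predictions otherwise.
    """

    def __init__(self, covariates=None, duration_col="time", event_col="event",
                 n_trees=500, min_node_size=15, mtry=None, seed=0, oob=True):
        self.covariates = covariates
        self.duration_col = duration_col
        self.event_col = event_col
        self.n_trees = n_trees
        self.min_node_size = min_node_size
        self.mtry = mtry
        self.seed = seed
        self.oob = oob

    def _covs(self, df):
        return list(self.covariates) if self.covariates is not None \
            else [c for c in COVARIATE_COLUMNS if c in df.columns]

    def fit(self, df: pd.DataFrame, y=None):
        try:
            from sksurv.ensemble import RandomSurvivalForest
            from sksurv.util import Surv
        except ImportError as exc:  # pragma: no cover
            raise CapabilityError(
                "scikit-survival is required for the RSF backend") from exc
        covs = self._covs(df)
        X = df[covs].to_numpy(dtype=float)
        if df[self.event_col].sum() < 1:
            raise ValueError("no events in the data")
        y_arr = Surv.from_arrays(event=df[self.event_col].astype(bool),
                                 time=df[self.duration_col].astype(float))
        self.model_ = RandomSurvivalForest(
            n_estimators=self.n_trees, min_samples_leaf=self.min_node_size,
            max_features=(self.mtry if self.mtry is not None else "sqrt"),
            random_state=self.seed, n_jobs=1)
        self.model_.fit(X, y_arr)
        self.covariates_ = covs
        self._train_X = X
        self.max_time_ = float(df[self.duration_col].max())
        return self

    def _oob_survival(self, horizon: float) -> np.ndarray | None:
        """Out-of-bag ensemble survival at a horizon for the training rows."""
        try:
            from sklearn.ensemble._forest import (
                _generate_unsampled_indices, _get_n_samples_bootstrap)
        except ImportError:
            return None
        n = self._train_X.shape[0]
        max_samples = getattr(self.model_, "max_samples", None)
        # newer scikit-learn versions thread sample_weight through these
        # private helpers; support both signatures
        try:
            n_boot = _get_n_samples_bootstrap(n, max_samples, None)
            def _unsampled(tree):
                return _generate_unsampled_indices(tree.random_state, n,
                                                   n_boot, None)
        except TypeError:
            n_boot = _get_n_samples_bootstrap(n, max_samples)
            def _unsampled(tree):
                return _generate_unsampled_indices(tree.random_state, n,
                                                   n_boot)
        total = np.zeros(n)
        counts = np.zeros(n)
        for tree in self.model_.estimators_:
            unsampled = _unsampled(tree)
            if len(unsampled) == 0:
                continue
            fns = tree.predict_survival_function(
                self._train_X[unsampled], return_array=False)
            total[unsampled] += [_eval_step(fn, horizon) for fn in fns]
            counts[unsampled] += 1
        if np.any(counts == 0):
            return None
        return total / counts

    def predict_survival(self, df: pd.DataFrame, horizon: float) -> np.ndarray:
        """Per-subject survival probability at ``horizon`` in [0, 1].

        Deterministic given the seed.  When ``oob`` is set and ``df`` has
        the same number of rows as the training data, out-of-bag ensemble
        predictions are returned for the training rows.
        """
        if horizon < 0:
            raise ValueError("horizon must be >= 0")
        X = df[self.covariates_].to_numpy(dtype=float)
        if self.oob and X.shape == self._train_X.shape and \
                np.array_equal(X, self._train_X):
            oob = self._oob_survival(horizon)
            if oob is not None:
                return np.clip(oob, 0.0, 1.0)
            import warnings
            warnings.warn("out-of-bag predictions unavailable; using the "
                          "full ensemble", RuntimeWarning, stacklevel=2)
        fns = self.model_.predict_survival_function(X, return_array=False)
        out = np.array([_eval_step(fn, horizon) for fn in fns])
        return np.clip(out, 0.0, 1.0)

    def config_metadata(self) -> dict:
        return asdict(RsfConfig(n_trees=self.n_trees,
                                min_node_size=self.min_node_size,
                                mtry=self.mtry, seed=self.seed))


def rsf_predict(df: pd.DataFrame, covariates=None,
                config: RsfConfig | None = None, horizon: float = 30.0,
                oob: bool = True) -> np.ndarray:
    """Fit a forest on the cohort and return survival probabilities at
    ``horizon`` (out-of-bag where available)."""
    config = config or RsfConfig()
    model = RandomSurvivalForestBackend(
        covariates=covariates, n_trees=config.n_trees,
        min_node_size=config.min_node_size, mtry=config.mtry,
        seed=config.seed, oob=oob).fit(df)
    return model.predict_survival(df, horizon)


__all__ = ["RsfConfig", "RandomSurvivalForestBackend", "rsf_predict",
           "CapabilityError"]
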