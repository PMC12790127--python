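"""Parametric learning-curve shapes.

Four classical families relate an operator's cumulative case volume ``n``
(first case is ``n = 1``) to the probability of procedural success:

* ``exponential``:   p(n) = a - (a - b) * exp(-c * (n - 1))
* ``power_series``:  p(n) = a - (a - b) * n**(-c)
* ``logarithmic``:   p(n) = b + c * ln(n)
* ``log_normal``:    p(n) = b + (a - b) * Phi((ln n - mu) / sigma)

``b`` is the success probability at the first case, ``a`` the asymptotic
plateau, ``c`` the learning rate.  All outputs are clamped to [0, 1] so they
remain valid probabilities (the logarithmic form is unbounded in ``n``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

SHAPE_KINDS = ("exponential", "power_series", "logarithmic", "log_normal")


@dataclass(frozen=True)
class ShapeSpec:
    """A learning-curve family with its parameters.

    ``asymptote``/``start``/``rate`` are the plateau ``a``, first-case value
    ``b`` and learning rate ``c``; ``mu``/``sigma`` apply to the log-normal
    family only.
    """

    kind: str
    asymptote: float = 0.85
    start: float = 0.60
    rate: float = 0.10
    mu: float = field(default=np.log(8.0))
    sigma: float = 1.0

    def __post_init__(self):
        if self.kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}; expected one of {SHAPE_KINDS}")
        if self.kind != "logarithmic":
            if not (0.0 <= self.asymptote <= 1.0 and 0.0 <= self.start <= 1.0):
                raise ValueError("asymptote and start must lie in [0, 1]")
        elif not 0.0 <= self.start <= 1.0:
            raise ValueError("start must lie in [0, 1]")
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def __call__(self, n):
        return shape_value(self, n)


def shape_value(spec: ShapeSpec, n):
    """Success probability at case order ``n`` (scalar or array), clamped to [0, 1]."""
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 1):
        raise ValueError("case order must be >= 1")
    a, b, c = spec.asymptote, spec.start, spec.rate
    if spec.kind == "exponential":
        p = a - (a - b) * np.exp(-c * (n_arr - 1.0))
    elif spec.kind == "power_series":
        p = a - (a - b) * n_arr ** (-c)
    elif spec.kind == "logarithmic":
        p = b + c * np.log(n_arr)
    else:  # log_normal
        p = b + (a - b) * stats.norm.cdf((np.log(n_arr) - spec.mu) / spec.sigma)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(n) or np.ndim(n) == 0 else p


def _pack(spec: ShapeSpec) -> np.ndarray:
    if spec.kind == "logarithmic":
        return np.array([spec.start, spec.rate])
    if spec.kind == "log_normal":
        return np.array([spec.asymptote, spec.start, spec.mu, spec.sigma])
    return np.array([spec.asymptote, spec.start, spec.rate])


def _unpack(kind: str, x: np.ndarray) -> ShapeSpec:
    if kind == "logarithmic":
        return ShapeSpec(kind, start=x[0], rate=x[1])
    if kind == "log_normal":
        return ShapeSpec(kind, asymptote=x[0], start=x[1], mu=x[2], sigma=max(x[3], 1e-6))
    return ShapeSpec(kind, asymptote=x[0], start=x[1], rate=max(x[2], 1e-9))


def _bounds(kind: str):
    if kind == "logarithmic":
        return np.array([0.0, 0.0]), np.array([1.0, 5.0])
    if kind == "log_normal":
        return np.array([0.0, 0.0, -3.0, 0.05]), np.array([1.0, 1.0, 8.0, 5.0])
    return np.array([0.0, 0.0, 1e-6]), np.array([1.0, 1.0, 10.0])


def fit_shape(orders, probabilities, kind: str, n_starts: int = 5,
              random_state: int | None = 0) -> tuple[ShapeSpec, float]:
    """Least-squares fit of one shape family to (order, probability) points.

    Multi-start bounded nonlinear least squares: one heuristic start from the
    data plus ``n_starts`` seeded random starts; the best local optimum wins.
    Returns ``(spec, residual_sum_of_squares)``.
    """
    orders = np.asarray(orders, dtype=float)
    probs = np.asarray(probabilities, dtype=float)
    if orders.shape != probs.shape:
        raise ValueError("orders and probabilities must have the same length")
    if np.any(orders < 1):
        raise ValueError("case order must be >= 1")
    lo, hi = _bounds(kind)
    n_params = len(lo)
    if len(np.unique(orders)) < n_params:
        raise ValueError(
            f"need at least {n_params} distinct case orders to fit a {kind} shape")

    if np.ptp(probs) == 0:
        # perfectly flat data: degenerate no-learning shape, zero residual
        level = float(probs[0])
        if kind == "logarithmic":
            return ShapeSpec(kind, start=level, rate=0.0), 0.0
        return ShapeSpec(kind, asymptote=level, start=level,
                         rate=1.0 if kind != "log_normal" else 0.1), 0.0

    def residuals(x):
        return shape_value(_unpack(kind, x), orders) - probs

    # heuristic start from early/late averages
    early = float(np.mean(probs[orders <= np.quantile(orders, 0.2)]))
    late = float(np.mean(probs[orders >= np.quantile(orders, 0.8)]))
    if kind == "logarithmic":
        slope = (late - early) / max(np.log(orders.max()), 1e-6)
        starts = [np.array([np.clip(early, 0, 1), np.clip(slope, 0, 5)])]
    elif kind == "log_normal":
        starts = [np.array([np.clip(late, 0, 1), np.clip(early, 0, 1),
                            np.log(max(np.median(orders), 1.1)), 1.0])]
    else:
        starts = [np.array([np.clip(late, 0, 1), np.clip(early, 0, 1), 0.1])]

    rng = np.random.default_rng(random_state)
    for _ in range(n_starts):
        starts.append(lo + rng.random(n_params) * (hi - lo))

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        try:
            res = optimize.least_squares(residuals, x0, bounds=(lo, hi),
                                         method="trf", xtol=1e-12, ftol=1e-12,
                                         gtol=1e-12)
        except Exception:
            continue
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[1]:
            best = (res.x, rss)
    if best is None:
        raise RuntimeError(f"shape fit failed for kind {kind!r}")
    return _unpack(kind, best[0]), best[1]


class ShapeCurve(BaseEstimator):
    """Scikit-learn-style estimator for one learning-curve family.

    Parameters
    ----------
    kind : str
        One of ``exponential``, ``power_series``, ``logarithmic``,
        ``log_normal``.
    n_starts : int
        Number of random multi-start initialisations for the bounded
        least-squares fit (in addition to a data-driven start).
    random_state : int
        Seed for the random starts.
    """

    def __init__(self, kind: str = "logarithmic", n_starts: int = 5,
                 random_state: int = 0):
        self.kind = kind
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X, y):
        orders = np.asarray(X, dtype=float).reshape(-1)
        spec, rss = fit_shape(orders, y, self.kind, n_starts=self.n_starts,
                              random_state=self.random_state)
        self.spec_ = spec
        self.rss_ = rss
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        orders = np.asarray(X, dtype=float).reshape(-1)
        return shape_value(self.spec_, orders)


def bin_observed(volumes, probabilities, bin_width: int = 5):
    """Binned averages of probabilities over half-open volume bins.

    Bins are ``[1, 1+w), [1+w, 1+2w), ...``; each returned point is
    ``(bin centre, mean probability)`` and empty bins are omitted, so a
    width of 1 reproduces the raw per-volume means.
    """
    if bin_width < 1:
        raise ValueError("bin width must be >= 1")
    volumes = np.asarray(volumes, dtype=float)
    probs = np.asarray(probabilities, dtype=float)
    if volumes.size == 0:
        return []
    idx = np.floor((volumes - 1.0) / bin_width).astype(int)
    points = []
    for k in np.unique(idx):
        mask = idx == k
        center = 1.0 + k * bin_width + (bin_width - 1) / 2.0
        points.append((float(center), float(probs[mask].mean())))
    return points


def flat_spec(kind: str, level: float) -> ShapeSpec:
    """A degenerate no-learning shape at a constant probability level."""
    if kind == "logarithmic":
        return ShapeSpec(kind, start=level, rate=0.0)
    return ShapeSpec(kind, asymptote=level, start=level)


__all__ = ["SHAPE_KINDS", "ShapeSpec", "ShapeCurve", "shape_value",
           "fit_shape", "bin_observed", "flat_spec", "replace"]
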