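"""Synthetic multi-center surgical cohort generator.

Emulates an external-ventricular-drain (EVD) stroke cohort: operators nested
in centers, a shared gamma frailty per operator, patient covariates drawn to
match the real cohort's published marginals, and a true learning effect that
enters the hazard through the operator's case order.  Event times are
exponential given the subject's hazard

    h = baseline_rate * w_operator * exp(beta' x) * g(case_order)

where ``g`` is the learning multiplier derived from a target learning-curve
shape: ``g(n) = -ln p(n) / (baseline_rate * learning_horizon)`` so that a
baseline subject's survival probability at the learning horizon traces the
target shape exactly.  Right censoring is independent exponential with a
rate calibrated by bisection to hit a requested censoring proportion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .shapes import ShapeSpec, shape_value


class InvalidConfigError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


# covariate columns in the fixed cohort CSV schema, in order
BINARY_COVARIATES = [
    "male", "diabetes", "stroke_history", "hypertension", "anticoagulant",
    "smoke", "cvd_history", "drug_history", "sah", "ivh", "ich",
    "device_bactericidal",
]
COVARIATE_COLUMNS = ["age"] + BINARY_COVARIATES + ["pre_op_mrs"]
COHORT_COLUMNS = (
    ["subject_id", "center_id", "operator_id", "case_order"]
    + COVARIATE_COLUMNS + ["time", "event"]
)


@dataclass(frozen=True)
class CovariateProfile:
    """Marginal distributions for the patient covariates.

    Defaults reproduce the real EVD cohort's published marginals (N = 160):
    age 57.5 (14.5) years, pre-op Modified Rankin Score 2.93 (1.67), and the
    binary prevalences below.  The drug-use history prevalence is not
    published; 0.20 is a plausible figure for this population.
    """

    age_mean: float = 57.5
    age_sd: float = 14.5
    mrs_mean: float = 2.93
    mrs_sd: float = 1.67
    binary_prevalences: dict = field(default_factory=lambda: {
        "male": 0.506,
        "diabetes": 0.125,
        "stroke_history": 0.113,
        "hypertension": 0.344,
        "anticoagulant": 0.275,
        "smoke": 0.488,
        "cvd_history": 0.150,
        "drug_history": 0.200,
        "sah": 0.525,
        "ivh": 0.406,
        "ich": 0.469,
        "device_bactericidal": 0.644,
    })

    def __post_init__(self):
        if self.age_sd <= 0:
            raise InvalidConfigError("age_sd must be positive")
        for name, p in self.binary_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError(f"prevalence of {name!r} outside [0, 1]")


# Modest log-hazard-ratio defaults mirroring the directions seen in the real
# adjusted Cox fit: strong smoking effect, a per-year age gradient, small
# effects elsewhere.  Ages and MRS enter centered at the profile means.
DEFAULT_BETA = {
    "age": 0.03,
    "smoke": float(np.log(2.0)),
    "stroke_history": 0.40,
    "anticoagulant": -0.45,
    "pre_op_mrs": 0.20,
    "device_bactericidal": 0.10,
}

DEFAULT_SHAPES = {
    "exponential": ShapeSpec("exponential", asymptote=0.85, start=0.60, rate=0.10),
    "power_series": ShapeSpec("power_series", asymptote=0.85, start=0.60, rate=0.70),
    "logarithmic": ShapeSpec("logarithmic", start=0.60, rate=0.07),
    "log_normal": ShapeSpec("log_normal", asymptote=0.85, start=0.60,
                            mu=float(np.log(8.0)), sigma=1.0),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """One data-generating condition.

    ``true_shape`` of ``None`` means no learning effect (``g == 1``).
    ``theta_true`` is the operator gamma-frailty variance; ``center_theta``
    an optional additional center-level frailty variance (default off).
    """

    n_centers: int = 4
    physicians_per_center: int = 10
    cases_per_physician: int = 25
    censoring_target: float = 0.10
    true_shape: ShapeSpec | None = DEFAULT_SHAPES["logarithmic"]
    beta_true: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    theta_true: float = 0.25
    center_theta: float = 0.0
    baseline_rate: float = 0.01
    learning_horizon: float = 30.0
    censoring_scheme: str = "exponential"
    seed: int = 0
    scenario_id: int | None = None

    def __post_init__(self):
        if min(self.n_centers, self.physicians_per_center,
               self.cases_per_physician) < 1:
            raise InvalidConfigError("counts must be positive")
        if not 0.0 < self.censoring_target < 1.0:
            raise InvalidConfigError("censoring_target must lie in (0, 1)")
        if self.theta_true < 0 or self.center_theta < 0:
            raise InvalidConfigError("frailty variances must be >= 0")
        if self.baseline_rate <= 0 or self.learning_horizon <= 0:
            raise InvalidConfigError("baseline_rate and learning_horizon must be positive")
        if self.censoring_scheme not in ("exponential", "administrative"):
            raise InvalidConfigError("censoring_scheme must be 'exponential' or 'administrative'")

    @property
    def n_subjects(self) -> int:
        return self.n_centers * self.physicians_per_center * self.cases_per_physician

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.true_shape is not None:
            d["true_shape"] = dataclasses.asdict(self.true_shape)
        return d


def true_learning_multiplier(shape: ShapeSpec | None, order,
                             baseline_rate: float = 0.01,
                             learning_horizon: float = 30.0):
    """Hazard multiplier implied by a target success-probability shape.

    Chosen so a baseline subject's survival at ``learning_horizon`` equals
    the shape's success probability at that case order; the multiplier
    decreases toward a positive floor as the operator gains experience.
    """
    order_arr = np.asarray(order, dtype=float)
    if np.any(order_arr < 1):
        raise ValueError("case order must be >= 1")
    if shape is None:
        g = np.ones_like(order_arr)
    else:
        p = np.clip(shape_value(shape, order_arr), 1e-9, 1.0 - 1e-12)
        g = -np.log(p) / (baseline_rate * learning_horizon)
    return float(g) if np.ndim(order) == 0 else g


def _draw_covariates(n: int, profile: CovariateProfile, rng) -> pd.DataFrame:
    cols = {"age": rng.normal(profile.age_mean, profile.age_sd, n)}
    for name in BINARY_COVARIATES:
        p = profile.binary_prevalences.get(name, 0.0)
        cols[name] = (rng.random(n) < p).astype(int)
    mrs = np.rint(rng.normal(profile.mrs_mean, profile.mrs_sd, n))
    cols["pre_op_mrs"] = np.clip(mrs, 0, 6).astype(int)
    return pd.DataFrame(cols)


def _linear_predictor(cov: pd.DataFrame, beta: dict, profile: CovariateProfile):
    eta = np.zeros(len(cov))
    for name, coef in beta.items():
        if coef == 0:
            continue
        if name not in cov.columns:
            raise InvalidConfigError(f"beta_true names unknown covariate {name!r}")
        x = cov[name].to_numpy(dtype=float)
        if name == "age":
            x = x - profile.age_mean
        elif name == "pre_op_mrs":
            x = x - profile.mrs_mean
        eta += coef * x
    return eta


def _uncensored_times(config: ScenarioConfig, profile: CovariateProfile, rng,
                      n_subjects=None):
    """Draw event times (and the frame of covariates/ids) without censoring."""
    n_ops = config.n_centers * config.physicians_per_center
    cases = config.cases_per_physician
    n = n_ops * cases if n_subjects is None else n_subjects

    center_of_op = np.repeat(np.arange(config.n_centers), config.physicians_per_center)
    w_op = (rng.gamma(1.0 / config.theta_true, config.theta_true, n_ops)
            if config.theta_true > 0 else np.ones(n_ops))
    w_center = (rng.gamma(1.0 / config.center_theta, config.center_theta, config.n_centers)
                if config.center_theta > 0 else np.ones(config.n_centers))

    op_idx = np.repeat(np.arange(n_ops), cases)[:n]
    order = np.tile(np.arange(1, cases + 1), n_ops)[:n]
    cov = _draw_covariates(n, profile, rng)
    eta = _linear_predictor(cov, config.beta_true, profile)
    g = true_learning_multiplier(config.true_shape, order,
                                 config.baseline_rate, config.learning_horizon)
    rate = (config.baseline_rate * w_op[op_idx] * w_center[center_of_op[op_idx]]
            * np.exp(eta) * g)
    t_event = rng.exponential(1.0 / rate)
    frame = cov.copy()
    frame.insert(0, "case_order", order)
    frame.insert(0, "operator_id",
                 [f"C{center_of_op[k] + 1:02d}-P{k % config.physicians_per_center + 1:02d}"
                  for k in op_idx])
    frame.insert(0, "center_id", [f"C{c + 1:02d}" for c in center_of_op[op_idx]])
    frame.insert(0, "subject_id", np.arange(1, n + 1))
    return frame, t_event, w_op


def _expected_censoring(param: float, times: np.ndarray, scheme: str) -> float:
    if scheme == "exponential":
        # C ~ Exp(param): P(C < T_i) = 1 - exp(-param * T_i)
        return float(np.mean(-np.expm1(-param * times)))
    # administrative: C ~ Uniform(0, 1/param): P(C < T_i) = min(param*T_i, 1)
    return float(np.mean(np.minimum(param * times, 1.0)))


def calibrate_censoring(event_times, target: float, tol: float = 0.03,
                        scheme: str = "exponential") -> float:
    """Censoring-rate parameter hitting a target censoring proportion.

    ``event_times`` is either an array of uncensored event times or a
    zero-argument callable producing one (n >= 2000 recommended).  For the
    exponential scheme the returned value is the censoring hazard rate; the
    expected censoring fraction ``mean(1 - exp(-rate * T_i))`` is monotone in
    the rate, so plain bisection applies.
    """
    if not 0.0 < target < 1.0:
        raise CalibrationError("target censoring must lie in (0, 1)")
    times = np.asarray(event_times() if callable(event_times) else event_times,
                       dtype=float)
    if times.size < 2 or np.any(times <= 0):
        raise CalibrationError("need positive uncensored event times")

    lo, hi = 1e-12, 1.0 / np.median(times)
    for _ in range(200):
        if _expected_censoring(hi, times, scheme) >= target:
            break
        hi *= 2.0
    else:
        raise CalibrationError(
            f"failed to bracket target {target}; expected censoring at rate "
            f"{hi:.3g} is {_expected_censoring(hi, times, scheme):.4f}")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _expected_censoring(mid, times, scheme) < target:
            lo = mid
        else:
            hi = mid
    rate = 0.5 * (lo + hi)
    achieved = _expected_censoring(rate, times, scheme)
    if abs(achieved - target) > tol:
        raise CalibrationError(
            f"calibration reached {achieved:.4f} for target {target} (tol {tol})")
    return rate


def generate_cohort(config: ScenarioConfig,
                    profile: CovariateProfile | None = None) -> pd.DataFrame:
    """Generate one synthetic cohort; deterministic given ``config.seed``.

    Returns a frame with the fixed column order ``COHORT_COLUMNS``: ids,
    case order (1..cases within each operator, in procedure-date order),
    covariates, observed ``time`` (days) and ``event`` indicator.
    """
    profile = profile or CovariateProfile()
    seed_root = np.random.SeedSequence(config.seed)
    calib_ss, cohort_ss = seed_root.spawn(2)

    # calibrate the censoring parameter on an independent uncensored sample
    calib_rng = np.random.default_rng(calib_ss)
    n_calib = max(2000, config.n_subjects)
    def _calib_sample():
        reps = int(np.ceil(n_calib / config.n_subjects))
        chunks = [
            _uncensored_times(config, profile, calib_rng)[1] for _ in range(reps)
        ]
        return np.concatenate(chunks)[:n_calib]
    cens_rate = calibrate_censoring(_calib_sample, config.censoring_target,
                                    tol=0.03, scheme=config.censoring_scheme)

    rng = np.random.default_rng(cohort_ss)
    frame, t_event, _ = _uncensored_times(config, profile, rng)
    if config.censoring_scheme == "exponential":
        c = rng.exponential(1.0 / cens_rate, len(frame))
    else:
        c = rng.uniform(0.0, 1.0 / cens_rate, len(frame))
    frame["time"] = np.minimum(t_event, c)
    frame["event"] = (t_event <= c).astype(int)
    frame.attrs["config"] = config.to_dict()
    frame.attrs["censoring_rate_param"] = cens_rate
    return frame[COHORT_COLUMNS]


__all__ = [
    "CovariateProfile", "ScenarioConfig", "InvalidConfigError",
    "CalibrationError", "DEFAULT_BETA", "DEFAULT_SHAPES", "COVARIATE_COLUMNS",
    "BINARY_COVARIATES", "COHORT_COLUMNS", "generate_cohort",
    "calibrate_censoring", "true_learning_multiplier",
]
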