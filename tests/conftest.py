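import numpy as np
import pandas as pd
import pytest

from frailcurve import ScenarioConfig, generate_cohort
from frailcurve.cohort import DEFAULT_SHAPES


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A modest clustered cohort with a true logarithmic learning effect."""
    cfg = ScenarioConfig(n_centers=2, physicians_per_center=5,
                         cases_per_physician=20, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort() -> pd.DataFrame:
    """Homogeneous cohort: no frailty, no covariate effects, no learning."""
    cfg = ScenarioConfig(n_centers=2, physicians_per_center=5,
                         cases_per_physician=30, theta_true=0.0,
                         beta_true={}, true_shape=None, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_config() -> ScenarioConfig:
    """Parameter-recovery DGP: 30 clusters x 40 subjects, theta = 0.5."""
    return ScenarioConfig(
        n_centers=6, physicians_per_center=5, cases_per_physician=40,
        theta_true=0.5, true_shape=None,
        beta_true={"age": 0.03, "smoke": float(np.log(2))},
        censoring_target=0.10, seed=0)


@pytest.fixture
def hand_cohort() -> pd.DataFrame:
    """Three subjects with one binary covariate; the Cox score equation
    solves in closed form to beta = -ln(2)/2."""
    return pd.DataFrame({"x": [1, 0, 1], "time": [1.0, 2.0, 3.0],
                         "event": [1, 1, 1]})
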