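import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from weakident.config import blood_config, sir_config, build_experiment


@pytest.fixture(scope="session")
def blood_experiment():
    """(model, system, times, truth, tf, w_true) for the default 40-obs blood study."""
    return build_experiment(blood_config())


@pytest.fixture(scope="session")
def blood_experiment_dense():
    """Blood study on a dense 400-point grid (accuracy checks)."""
    return build_experiment(blood_config(n_obs=400))


@pytest.fixture(scope="session")
def sir_experiment():
    """(model, system, times, truth, tf, w_true) for the 31-day SIR study."""
    return build_experiment(sir_config())
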