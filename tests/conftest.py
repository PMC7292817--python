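import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from benchval import CVSimConfig, calibrate_separation, run_cv_experiment

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cv_config():
    """Reference CV-coverage experiment configuration (3-fold, n_train=300)."""
    return CVSimConfig(n_train=300, runs=1000, seed=20260101)


@pytest.fixture(scope="session")
def calibrated_separation(cv_config):
    """Class separation calibrated so the trained linear SVM hits AUC 0.75."""
    return calibrate_separation(cv_config)


@pytest.fixture(scope="session")
def coverage_report(cv_config, calibrated_separation):
    """The full 1000-run coverage experiment, shared across tests."""
    return run_cv_experiment(cv_config, separation=calibrated_separation)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
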