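import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import synpolarity as sp
from synpolarity.objective import PanelEvaluator

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def circuit():
    return sp.default_connectome()


@pytest.fixture(scope="session")
def truth8():
    """Planted all-inhibitory truth with the 8 strongest connections free."""
    return sp.make_truth("optimal", seed=1, n_free=8)


@pytest.fixture(scope="session")
def truth_full():
    """Planted all-inhibitory truth with all 26 above-cutoff connections free."""
    return sp.make_truth("optimal", seed=1)


@pytest.fixture(scope="session")
def clean_data8(truth8):
    return sp.make_behavioral_data(truth8, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def noisy_data8(truth8):
    return sp.make_behavioral_data(truth8, noise_sd=0.02, seed=1)


@pytest.fixture(scope="session")
def ev8(truth8, noisy_data8):
    return PanelEvaluator(truth8.connectome, truth8.connset, noisy_data8)


@pytest.fixture(scope="session")
def ev8_clean(truth8, clean_data8):
    return PanelEvaluator(truth8.connectome, truth8.connset, clean_data8)
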