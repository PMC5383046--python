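import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import triagenlp as tn

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_records():
    """400-visit synthetic cohort shared across tests."""
    return tn.generate_dataset(tn.SyntheticConfig(n_visits=400, seed=11))


@pytest.fixture(scope="session")
def medium_records():
    """5,000-visit cohort for convergence-style checks."""
    return tn.generate_dataset(tn.SyntheticConfig(n_visits=5000, seed=23))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
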