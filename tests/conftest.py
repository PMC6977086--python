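import numpy as np
import pytest

from betaevents import SimulationConfig, generate_session


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_subjects_per_group=2, n_trials=20, seed=0)


@pytest.fixture(scope="session")
def small_session(small_config):
    """One simulated control subject (envelope mode) reused across tests."""
    return generate_session(small_config, "s00", "control", seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
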