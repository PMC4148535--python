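import numpy as np
import pytest

from emgkin import SimulationConfig, make_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A short default-condition synthetic recording shared across tests."""
    return make_dataset(SimulationConfig(duration=20.0, seed=7))


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Realizable data: no angle noise; drive known exactly."""
    return make_dataset(SimulationConfig(duration=20.0, seed=11, angle_noise_std=0.0))
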