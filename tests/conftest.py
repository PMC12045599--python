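import numpy as np
import pytest

from invkit.synthetic_data import SimulationConfig, simulate_fixed_capture_pair


@pytest.fixture(scope="session")
def noise_free_config() -> SimulationConfig:
    """A small, fully deterministic field: no shot noise, no read noise."""
    return SimulationConfig(n_cells=4, image_shape=(320, 320),
                            noise_sd=0.0, photon_scale=0.0, seed=11)


@pytest.fixture(scope="session")
def noise_free_pair(noise_free_config):
    return simulate_fixed_capture_pair(noise_free_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
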