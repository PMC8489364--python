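import numpy as np
import pytest

from qctpeep import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def noiseless_config() -> PhantomConfig:
    """Default study conditions without HU noise, on a small grid for speed."""
    return PhantomConfig(grid_shape=(40, 40, 40), voxel_size=(3.0, 3.0, 3.0), hu_noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_config):
    return generate_phantom(noiseless_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20231107)
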