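import numpy as np
import pytest

from nanocoloc import ConditionLabel, SyntheticConfig, generate_fov


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_config():
    """A light configuration for tests that just need a plausible FOV."""
    return SyntheticConfig(image_shape=(128, 128), n_cells_mean=10, n_cells_sd=3, seed=11)


@pytest.fixture(scope="session")
def hm_fov(small_config):
    """One rendered high-uptake FOV with its ground truth."""
    cond = ConditionLabel("HM", "pbs", 200, 37)
    return generate_fov(small_config, cond)
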