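import numpy as np
import pytest
from hypothesis import settings

from ichseg.phantom import PhantomConfig, generate_dataset, generate_volume

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """Small, fast phantom profile shared across unit tests."""
    return PhantomConfig(image_size=32, n_slices=8)


@pytest.fixture(scope="session")
def ich_volume(small_config):
    return generate_volume(small_config, with_ich=True, seed=11)


@pytest.fixture(scope="session")
def healthy_volume(small_config):
    return generate_volume(small_config, with_ich=False, seed=12)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """10 small volumes (5 with hemorrhage) plus manifest."""
    return generate_dataset(small_config, 10, seed=21)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
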