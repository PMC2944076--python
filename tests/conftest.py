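import numpy as np
import pytest

from airburden import SyntheticWorldConfig, gen_world


@pytest.fixture(scope="session")
def small_config():
    return SyntheticWorldConfig(
        seed=7, n_lat=16, n_lon=32, n_countries=12, pollution_hotspot_count=8,
        unavailable_fraction=0.25,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """A 16x32 synthetic world shared across tests (read-only)."""
    return gen_world(small_config)


@pytest.fixture(scope="session")
def medium_world():
    """A 32x64 world for tests needing more spatial structure."""
    return gen_world(
        SyntheticWorldConfig(seed=11, n_lat=32, n_lon=64, n_countries=24,
                             pollution_hotspot_count=15)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
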