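import numpy as np
import pytest

from plastisink import KooiParams
from plastisink.fields import SyntheticWorldConfig, generate_synthetic_ocean


@pytest.fixture(scope="session")
def params() -> KooiParams:
    return KooiParams()


@pytest.fixture(scope="session")
def world():
    """The default-resolution synthetic global ocean (seed 1), shared."""
    return generate_synthetic_ocean(seed=1)


@pytest.fixture(scope="session")
def world_config() -> SyntheticWorldConfig:
    return SyntheticWorldConfig()


@pytest.fixture(scope="session")
def coarse_world_config() -> SyntheticWorldConfig:
    """A desk-size world for tests that write files or scan many points."""
    return SyntheticWorldConfig(
        lon_step=10.0,
        lat_step=10.0,
        depth_levels=(0.6, 10.0, 30.0, 60.0, 100.0, 200.0, 400.0, 800.0),
        n_time=12,
        days_per_step=30.0,
        year_days=360.0,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
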