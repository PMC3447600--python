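import numpy as np
import pytest

from ecoca.grid import DEFAULT_SCHEME, LandUseGrid
from ecoca.synth import SyntheticSpec, generate_bundle


@pytest.fixture(scope="session")
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture(scope="session")
def small_spec():
    """Small lattice for fast structural tests."""
    return SyntheticSpec(
        shape=(120, 120),
        seed=7,
        n_towns=20,
        n_highways=6,
        n_rivers=5,
        n_idw_points=12,
        n_dem_bumps=6,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return generate_bundle(small_spec)


@pytest.fixture(scope="session")
def default_bundle():
    """The default study-condition bundle used by the acceptance checks."""
    return generate_bundle(SyntheticSpec(seed=1))


def random_map(rng, shape=(30, 30), codes=(1, 2, 3, 4)):
    return LandUseGrid(rng.choice(codes, size=shape).astype(np.int64))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
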