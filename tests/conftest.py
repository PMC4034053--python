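import numpy as np
import pytest

from fgspike.network import NetworkConfig
from fgspike.stimuli import (
    ProfileSpec,
    default_circle_sets,
    default_fixtures,
    generate_polygon_stimulus,
    make_image_set,
)


@pytest.fixture(scope="session")
def fixture_sets():
    return default_fixtures()


@pytest.fixture(scope="session")
def circle_sets():
    return default_circle_sets()


@pytest.fixture(scope="session")
def config():
    return NetworkConfig()


def small_profile(n: int = 32) -> ProfileSpec:
    """Asymmetric smooth profile for the half-scale test stimulus."""
    cols = [16] + [14] * 5 + [12] * 8 + [11] * 8 + [13] * 9 + [16]
    assert len(cols) == n
    return ProfileSpec(tuple(cols), "left")


@pytest.fixture(scope="session")
def small_set():
    """Half-scale polygon set (n=32, m=3, white 430).

    Same inner/outer proportions as the full fixtures (32/38 = 64/76), so
    the network operates in the same excitation/inhibition regime while
    runs stay fast.
    """
    img = generate_polygon_stimulus(small_profile(), n=32, m=3, target_white=430)
    return make_image_set(img, label="small")


@pytest.fixture
def rng():
    return np.random.default_rng(20240527)

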