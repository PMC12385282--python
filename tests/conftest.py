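import numpy as np
import pytest

from pestmap.hypercube import Hypercube
from pestmap.synthetic import SceneSpec, make_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cube(rng):
    """4x5 pixels x 6 bands of random reflectance."""
    wl = 900.0 + 10.0 * np.arange(6)
    return Hypercube(rng.uniform(0.05, 0.9, (4, 5, 6)), wl)


@pytest.fixture(scope="session")
def noiseless_scene():
    """Deterministic 32x32 two-endmember scene without noise."""
    return make_scene(SceneSpec(shape=(32, 32), noise_sd=0.0, seed=2))


@pytest.fixture(scope="session")
def noisy_scene():
    """Deterministic 32x32 scene with 1%-of-mean-signal Gaussian noise."""
    return make_scene(SceneSpec(shape=(32, 32), noise_sd=0.01, seed=2))
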