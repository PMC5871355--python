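import warnings

import numpy as np
import pytest

from cnmfe.movie import Movie
from cnmfe.simulate import SimConfig, simulate_movie

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: results do not depend on the
    # order in which tests run
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """A 64x64 x 1000-frame scene with 10 neurons, background and vessel."""
    cfg = SimConfig(fov_shape=(64, 64), n_frames=1000, n_neurons=10,
                    n_bg_sources=5, vessel=True, seed=3)
    movie, truth = simulate_movie(cfg)
    return movie, truth


@pytest.fixture(scope="session")
def clean_single_neuron():
    """One isolated neuron, no background sources, noise-free-ish scene."""
    cfg = SimConfig(fov_shape=(40, 40), n_frames=600, n_neurons=1,
                    n_bg_sources=0, vessel=False, seed=7)
    movie, truth = simulate_movie(cfg)
    return movie, truth


@pytest.fixture()
def tiny_movie():
    """Deterministic 8x8 x 64-frame movie of smooth positive values."""
    rng = np.random.default_rng(0)
    data = 1.0 + 0.1 * rng.random((64, 64)).astype(np.float32)
    return Movie(data, (8, 8))
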