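import numpy as np
import pytest

from rseitools import SceneConfig
from rseitools.synthetic_scene import _truth_from_landcover, generate_landcover


def zero_slopes():
    return {}


@pytest.fixture
def scene_factory():
    """Build (cfg, truth) pairs with overridable scene parameters."""

    def make(**overrides):
        defaults = dict(grid_shape=(32, 32), n_years=3, obs_per_season=12, seed=7)
        defaults.update(overrides)
        cfg = SceneConfig(**defaults)
        lc = generate_landcover(cfg)
        truth = _truth_from_landcover(cfg, lc)
        return cfg, truth

    return make


@pytest.fixture
def clean_scene(scene_factory):
    """Noise-free, gap-free, trend-free scene: exactly one harmonic per pixel."""
    return scene_factory(noise_sd={}, gap_fraction=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
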