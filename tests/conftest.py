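import numpy as np
import pytest

from grainscan import synth
from grainscan.scan_io import mm_per_pixel

MM600 = mm_per_pixel(600.0)
MM150 = mm_per_pixel(150.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_dist():
    return synth.GrainDistribution()


@pytest.fixture
def grain_600dpi(rng):
    """One typical grain rendered at scanner resolution."""
    model = synth.GrainModel(8.6, 2.8, orientation=0.6, shape_n=2.5, noise_sd=5.0)
    crop, mask = synth.render_grain(model, MM600, rng=rng)
    return model, crop, mask


@pytest.fixture
def small_scene(rng):
    """A 30-grain non-overlapping scene at the coarse working resolution."""
    img, ann = synth.generate_scene(
        30, synth.OcclusionConfig(max_ratio=0.0), MM150, rng, canvas=(900, 900)
    )
    return img, ann
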