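import numpy as np
import pytest

from pmmd.raster import RasterImage
from pmmd.synthetic import CohortConfig, generate_handwriting_page, generate_spiral_pair


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_config():
    """A fast, small-image cohort configuration for unit tests."""
    return CohortConfig(n_pd=3, n_hc=3, image_size=128, seed=7)


@pytest.fixture
def pd_spiral_pair(small_config):
    return generate_spiral_pair(small_config, "PD", seed=11)


@pytest.fixture
def clean_page():
    """A deterministic handwriting page without class perturbations."""
    cfg = CohortConfig(
        pressure_jitter_pd=0.0, slant_jitter_pd=0.0, baseline_wobble_pd=0.0,
        word_gap_mean_pd=20.0, severity_spread=0.0,
    )
    return generate_handwriting_page(cfg, "PD", seed=3)


def random_image(rng, shape=(64, 64)) -> RasterImage:
    return RasterImage(rng.integers(0, 256, shape).astype(np.uint8))
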