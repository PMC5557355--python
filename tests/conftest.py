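import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_field_spec():
    """Small, well-separated, noise-free puncta field for exact recovery."""
    from synaptoquant.synthgen import PunctaFieldSpec

    return PunctaFieldSpec(
        image_shape_px=(768, 768),
        n_red=50,
        n_green=0,
        pairing_fraction=0.0,
        poisson_noise=False,
        gaussian_noise_sd=0.0,
        # without noise the automatic threshold sits just above the flat
        # background, so the blur tails reach further than in noisy images;
        # spread the spots accordingly
        min_separation_factor=8.0,
        seed=42,
    )
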