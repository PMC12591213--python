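import numpy as np
import pytest

from ecmorph.synthetic import FiberSpec, render_image


@pytest.fixture(scope="session")
def single_fiber_image():
    """One straight mature fiber, noise-free, on a small field."""
    fiber = FiberSpec(
        anchor_um=(64.0, 64.0), orientation=0.3, length_um=50.0,
        width_um=3.0, waviness=0.0, stain="mature",
    )
    img, truth = render_image(
        [fiber], pixel_size_um=0.5, shape=(256, 256), noise_sigma=0.0
    )
    return img, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
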