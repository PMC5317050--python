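import numpy as np
import pytest

from cellquant import AcquisitionSpec, SceneSpec, generate_scene, render_image
from cellquant.crf import CRFModel, InverseLUT


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def identity_lut():
    return InverseLUT.identity()


def random_valid_cubic(rng) -> CRFModel:
    """Random monotone cubic with f(0)=0, f(1)=1 (rejection sampling)."""
    while True:
        b1, b2 = rng.uniform(-3.0, 3.0, size=2)
        model = CRFModel(np.array([0.0, b1, b2, 1.0 - b1 - b2]))
        if model.is_valid():
            return model


@pytest.fixture
def small_scene():
    """A modest field of rods with known ground truth (low noise)."""
    spec = SceneSpec(
        image_height_px=256, image_width_px=256, n_cells=25, noise_sd=2.0, seed=42
    )
    return generate_scene(spec)


def default_render(truth, **acq_kwargs):
    return render_image(truth, AcquisitionSpec(**acq_kwargs))
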