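import numpy as np
import pytest

from ductstone.network import ModelConfig
from ductstone.phantom import PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_phantom_cfg():
    """48px phantoms with small stones; fast to draw in bulk."""
    return PhantomConfig(width=48, height=48, stone_radius_range=(2.0, 4.0), seed=7)


@pytest.fixture
def tiny_model_cfg():
    """A miniature detector for 32px inputs (fast unit-test forward passes)."""
    return ModelConfig(
        image_size=32,
        backbone_channels=(4, 6, 8),
        convs_per_block=1,
        dropout=0.0,
        c_d=4,
        decoder_channels=(8, 8, 8),
        classifier_hidden=16,
        seed=3,
    )


def numerical_gradient(f, x, eps=1e-6):
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f(x)
        x[i] -= 2 * eps
        fm = f(x)
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g
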