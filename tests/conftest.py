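import numpy as np
import pytest

from scramblenet import PhantomSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_image(rng):
    """A random 8-bit 64x64 grid."""
    return rng.integers(0, 256, size=(64, 64), dtype=np.uint8)


@pytest.fixture
def smooth_phantom():
    """A noiseless smooth tumor phantom (high adjacent-pixel correlation)."""
    spec = PhantomSpec(side=64, noise_sigma=0.0, seed=0)
    return make_phantom(spec, "yes", np.random.default_rng(0))
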