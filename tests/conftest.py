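import numpy as np
import pytest

from choroidtex.synthetic import PhantomSpec, generate_bscan


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom():
    """A small noise-free phantom with a few vessels, cheap enough for units."""
    spec = PhantomSpec(height=128, width=200, rpe_curve_coeffs=(30.0,),
                       vessel_count=6, sp_noise_density=0.0, seed=3)
    image, truth = generate_bscan(spec)
    return spec, image, truth
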