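import numpy as np
import pytest

from mslesseg.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A small noiseless phantom with three well-separated lesions."""
    spec = PhantomSpec(
        grid_shape=(40, 40, 40), n_lesions=3,
        lesion_radius_range=(2.0, 3.5), black_hole_fraction=0.34,
        noise_sd=0.0, seed=7, non_overlapping=True,
    )
    return spec, *make_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
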