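import numpy as np
import pytest

from tomocell.phantom import PhantomSpec, generate_phantom, probabilities_from_truth


@pytest.fixture(scope="session")
def small_phantom():
    """A 100³ phantom with 15 cells and one vessel at the default 4.6 dB SNR."""
    spec = PhantomSpec(shape_vox=(100, 100, 100), n_cells=15, n_vessels=1, seed=3)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_truth_maps(small_phantom):
    """Idealized probability maps derived from the small phantom's truth."""
    return probabilities_from_truth(
        small_phantom.truth_masks, blur_sigma=1.0, flip_noise=0.02, seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
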