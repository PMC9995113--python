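import numpy as np
import pytest

from glymphokit.synthetic import PhantomSpec, gen_ciss_phantom


@pytest.fixture(scope="session")
def small_noiseless_phantom():
    """64^3 noiseless CISS phantom shared across segmentation tests."""
    spec = PhantomSpec(seed=7, grid_shape=(64, 64, 64), snr=np.inf)
    return gen_ciss_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
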