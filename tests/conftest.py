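import numpy as np
import pytest

from subdki import PhantomSpec, connectome_scheme, make_phantom


@pytest.fixture(scope="session")
def connectome():
    return connectome_scheme()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default two-tissue checkerboard phantom without noise."""
    spec = PhantomSpec(snr=None, seed=0)
    ds, truth = make_phantom(spec)
    return ds, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
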