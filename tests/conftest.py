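import numpy as np
import pytest

from corti.synth import gerbil_params, mouse_params


@pytest.fixture(scope="session")
def gerbil_nf():
    """Noise-free gerbil preset (deterministic descriptors)."""
    return gerbil_params().noise_free()


@pytest.fixture(scope="session")
def mouse_nf():
    return mouse_params().noise_free()


@pytest.fixture(scope="session")
def gerbil_default():
    return gerbil_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
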