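import numpy as np
import pytest

import mrftv


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def shepp64():
    """Clean 64x64 ellipse phantom magnitude in [0, 255]."""
    spec = mrftv.PhantomSpec(shape=(64, 64), kind="shepp_logan", seed=0)
    return np.abs(mrftv.make_phantom(spec))


@pytest.fixture(scope="session")
def texture64():
    spec = mrftv.PhantomSpec(shape=(64, 64), kind="piecewise_texture", seed=0)
    return np.abs(mrftv.make_phantom(spec))


@pytest.fixture(scope="session")
def texture128():
    spec = mrftv.PhantomSpec(shape=(128, 128), kind="piecewise_texture",
                             seed=0)
    return np.abs(mrftv.make_phantom(spec))
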