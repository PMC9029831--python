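import numpy as np
import pytest

from pmfsurf import benchmark as B
from pmfsurf.synth import make_surface


@pytest.fixture(scope="session")
def coarse_grid():
    return B.coarse_grid()


@pytest.fixture(scope="session")
def fine_grid():
    return B.fine_grid()


@pytest.fixture(scope="session")
def three_well_surface():
    return make_surface(B.three_well_spec())


@pytest.fixture()
def rng():
    return np.random.default_rng(20220412)
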