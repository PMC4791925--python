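import numpy as np
import pytest

from epigames.networks import build_grid_lattice


@pytest.fixture(scope="session")
def grid5():
    return build_grid_lattice(5)


@pytest.fixture(scope="session")
def grid3():
    return build_grid_lattice(3)


@pytest.fixture(scope="session")
def grid61():
    return build_grid_lattice(61)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
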