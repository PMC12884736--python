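import numpy as np
import pytest

from surfscan import synthetic
from surfscan.calibration import intrinsic_matrix
from surfscan.trajectory import OBJECTIVE_PRESETS


@pytest.fixture(scope="session")
def plane_mesh():
    return synthetic.make_surface("plane", {"extent": 10.0, "spacing": 0.5})


@pytest.fixture(scope="session")
def small_plane_mesh():
    return synthetic.make_surface("plane", {"extent": 2.0, "spacing": 0.25})


@pytest.fixture(scope="session")
def hemisphere_mesh():
    return synthetic.make_surface("hemisphere", {"radius": 7.5})


@pytest.fixture(scope="session")
def bumpy_mesh():
    return synthetic.make_surface("bumpy", {"extent": 12.0, "spacing": 0.5, "amplitude": 2.0}, seed=11)


@pytest.fixture(scope="session")
def intrinsics_5x():
    return intrinsic_matrix(5.0, 4.5)


@pytest.fixture(scope="session")
def objective_5x():
    return OBJECTIVE_PRESETS["5x"]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
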