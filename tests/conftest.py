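import numpy as np
import pytest

from srcfc.forward import (HeadModel, build_source_grid, compute_leadfield,
                           head_model_preset)
from srcfc.simulate import make_sensor_array


@pytest.fixture(scope="session")
def head12():
    return head_model_preset(12)


@pytest.fixture(scope="session")
def coarse_grid(head12):
    """15-mm lattice: ~350 sources, enough for inverse/parcellation tests."""
    return build_source_grid(head12, 15.0)


@pytest.fixture(scope="session")
def sensors32():
    return make_sensor_array(32)


@pytest.fixture(scope="session")
def sensors64():
    return make_sensor_array(64)


@pytest.fixture(scope="session")
def leadfield_coarse(head12, coarse_grid, sensors32):
    return compute_leadfield(head12, coarse_grid, sensors32)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
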