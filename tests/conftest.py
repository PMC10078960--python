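import numpy as np
import pytest

from thoraxvar.parametric_model import ParameterVector, default_parameter_space
from thoraxvar.surrogate import calibrate_load, default_load_case


@pytest.fixture(scope="session")
def space():
    return default_parameter_space()


@pytest.fixture(scope="session")
def cut_point(space):
    return ParameterVector.cut_point(space)


@pytest.fixture(scope="session")
def frontal_case():
    return calibrate_load(default_load_case("frontal"))


@pytest.fixture(scope="session")
def near_side_case():
    return calibrate_load(default_load_case("near_side"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
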