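import numpy as np
import pytest

from radiopeek.materials import (
    Material,
    parse_formula,
    study_materials,
    weight_fractions,
)
from radiopeek.synthetic import build_default_library


@pytest.fixture(scope="session")
def mats():
    """The six study materials."""
    return study_materials()


@pytest.fixture(scope="session")
def library():
    return build_default_library()


@pytest.fixture(scope="session")
def water():
    return Material("water", weight_fractions(parse_formula("H2O")), density=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
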