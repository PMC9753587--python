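import numpy as np
import pytest

from sugarcg.graph import parse_glycan
from sugarcg.mapping import build_mapping_index


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def glucose_graph():
    return parse_glycan("GLC")


@pytest.fixture
def glucose_index(glucose_graph):
    return build_mapping_index(glucose_graph)


@pytest.fixture
def lactose_graph():
    return parse_glycan("GAL(b1-4)GLC")
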