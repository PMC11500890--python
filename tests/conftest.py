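import numpy as np
import pytest

from dentmatch.dentition import default_transition_graph
from dentmatch.similarity import ScoringParams


@pytest.fixture(scope="session")
def graph():
    return default_transition_graph()


@pytest.fixture(scope="session")
def params():
    return ScoringParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
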