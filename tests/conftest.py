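import numpy as np
import pytest

from famexpand.family_data import read_newick
from famexpand.gt61 import angiosperm_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return angiosperm_taxonomy()


@pytest.fixture(scope="session")
def uniform_pi():
    return np.full(61, 1.0 / 61.0)


@pytest.fixture
def six_leaf_tree():
    """Balanced six-leaf tree: two monocot pairs plus two dicots."""
    return read_newick(
        "(((a_MUSAC:0.3,b_ORYSA:0.3):0.2,(c_PHODA:0.25,d_ELAGV:0.25):0.2):0.15,"
        "(e_ARATH:0.35,f_VITVI:0.35):0.25);"
    )


@pytest.fixture
def three_leaf_tree():
    return read_newick("((a_MUSAC:0.2,b_ARATH:0.35):0.1,c_AMBTC:0.4);")
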