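import numpy as np
import pytest

from jointfold.params import default_parameter_set
from jointfold.phylo import PhyloTree
from jointfold.thermo import EnergyModel


@pytest.fixture(scope="session")
def models():
    return default_parameter_set()


@pytest.fixture(scope="session")
def energy():
    return EnergyModel()


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def two_leaf_tree(b1=0.1, b2=0.15, taxa=("t0", "t1")):
    return PhyloTree(list(taxa), [[], [], [0, 1]], np.array([b1, b2, 0.0]), 2)


def three_leaf_tree(taxa=("t0", "t1", "t2")):
    return PhyloTree(
        list(taxa), [[], [], [], [0, 1], [3, 2]],
        np.array([0.1, 0.12, 0.2, 0.05, 0.0]), 4,
    )


@pytest.fixture
def tree2():
    return two_leaf_tree()


@pytest.fixture
def tree3():
    return three_leaf_tree()
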