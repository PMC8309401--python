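import numpy as np
import pytest

from floracues.phylo import PhyloTree
from floracues.synth import gen_yule_tree


@pytest.fixture
def three_tip_tree():
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four():
    return PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def yule14():
    return gen_yule_tree(14, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
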