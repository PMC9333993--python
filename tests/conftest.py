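import numpy as np
import pytest

from mosaicbrain import phylo
from mosaicbrain import simulate as sim


@pytest.fixture
def cherry3():
    """((A,B),C) with depths 2 everywhere — the workhorse 3-tip fixture."""
    return phylo.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced4():
    return phylo.read_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")


@pytest.fixture
def star4():
    return phylo.read_newick("(A:1,B:1,C:1,D:1);")


@pytest.fixture
def tree20():
    return sim.simulate_tree(20, 1.0, 0.0, seed=20)


@pytest.fixture
def tree32():
    return sim.simulate_tree(32, 1.0, 0.0, seed=32)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
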