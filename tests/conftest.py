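import numpy as np
import pytest

import mixclock as mc
from mixclock.gtr import build_gtr
from mixclock.simulate import default_gtr


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def three_taxon_tree():
    return mc.read_newick("((A:10,B:10):10,C:20);")


@pytest.fixture
def gtr_q():
    return build_gtr(default_gtr())


@pytest.fixture
def jc_q():
    return build_gtr(mc.GTRParams.jc())


@pytest.fixture
def yule_tree(rng):
    return mc.simulate_yule_tree(0.05, 40.0, 6, rng)
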