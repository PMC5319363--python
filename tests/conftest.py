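import numpy as np
import pytest

from radiad.synth import simulate_bd_tree, SyntheticScenario, make_scenario
from radiad.tree import tree_from_newick


@pytest.fixture
def tiny_tree():
    return tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_tip_tree():
    return tree_from_newick("(((A:1,B:1):1,C:2):1,D:3);")


@pytest.fixture(scope="session")
def yule_tree_60():
    return simulate_bd_tree(0.15, 0.0, stop="tips", tips=60, seed=101)


@pytest.fixture(scope="session")
def bd_tree_10():
    return simulate_bd_tree(0.15, 0.05, stop="tips", tips=10, seed=7)


@pytest.fixture(scope="session")
def bd_tree_80():
    return simulate_bd_tree(0.15, 0.05, stop="tips", tips=80, seed=31)


@pytest.fixture(scope="session")
def small_bundle():
    sc = SyntheticScenario(
        seed=9, clade_sizes=(40, 10), n_posterior=4, n_extinct=6,
        crown_age=45.0,
    )
    return make_scenario(sc)
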