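import numpy as np
import pytest

from phyloenv.trees import Phylogeny, read_newick, simulate_yule_tree
from phyloenv.synthetic import er_rate_matrix, scale_tree, simulate_regime_history


@pytest.fixture(scope="session")
def three_tip_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def yule50():
    return simulate_yule_tree(50, seed=101)


@pytest.fixture(scope="session")
def painted_five_tip():
    """A fixed 5-tip ultrametric tree painted with a 2-state history."""
    tree = scale_tree(simulate_yule_tree(5, seed=11), 1.0)
    hist = simulate_regime_history(tree, er_rate_matrix(2, 1.0), 0, seed=12)
    return hist


def star_tree(n: int, depth: float = 1.0) -> Phylogeny:
    parent = np.full(n + 1, n)
    parent[-1] = -1
    blen = np.full(n + 1, depth)
    blen[-1] = 0.0
    return Phylogeny([f"s{i}" for i in range(n)], parent, blen)
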