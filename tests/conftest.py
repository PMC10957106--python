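import numpy as np
import pytest

from phyloturn.simulate import SimulationConfig, simulate_tree
from phyloturn.trees import TimeTree


@pytest.fixture
def balanced_tree() -> TimeTree:
    """4-tip balanced ultrametric tree: root at 40, inner nodes at 10."""
    return TimeTree.from_newick("((A:10,B:10):30,(C:10,D:10):30);")


@pytest.fixture
def five_tip_tree() -> TimeTree:
    return TimeTree.from_newick("((A:1,B:1):1,(C:2,(D:1,E:1):1):0.5);")


@pytest.fixture
def star_tree() -> TimeTree:
    return TimeTree.from_newick("(A:1,B:1,C:1,D:1,E:1);")


def random_tree(seed: int, n_tips: int = 20) -> TimeTree:
    """Convenience wrapper: a seeded birth-death tree."""
    return simulate_tree(SimulationConfig(n_tips=n_tips, seed=seed))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260918)
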