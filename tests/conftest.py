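import numpy as np
import pandas as pd
import pytest

import phylosoil as ps


@pytest.fixture
def cherry_pair_tree():
    """Two cherries: ((A:1,B:1):1,(C:1,D:1):1); — the worked example."""
    return ps.read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def cherry_pair_traits():
    return pd.Series({"A": 0.0, "B": 0.0, "C": 10.0, "D": 10.0})


@pytest.fixture
def tiny_grid():
    """2x2 grid of 20 m cells, one variable, one missing cell."""
    arr = np.array([[1.0, 3.0], [5.0, np.nan]])
    return ps.SoilGrid(20.0, {"P": arr})


def random_tree(rng: np.random.Generator, n_tips: int, polytomy_prob: float = 0.3):
    """Random rooted tree with random branch lengths; polytomies allowed.

    Built by recursive partitioning of the tip label set, independent of
    the package's Yule simulator.
    """
    from phylosoil.treeio import Node, Phylogeny

    labels = [f"t{i}" for i in range(n_tips)]

    def build(members, is_root=False):
        node = Node(length=None if is_root else float(rng.uniform(0.05, 2.0)))
        if len(members) == 1:
            node.label = members[0]
            return node
        max_parts = min(len(members), 4)
        n_parts = 2
        if max_parts > 2 and rng.random() < polytomy_prob:
            n_parts = int(rng.integers(3, max_parts + 1))
        cuts = sorted(rng.choice(np.arange(1, len(members)), size=n_parts - 1,
                                 replace=False))
        parts, prev = [], 0
        for c in list(cuts) + [len(members)]:
            parts.append(members[prev:c])
            prev = c
        for part in parts:
            node.add_child(build(part))
        return node

    shuffled = list(rng.permutation(labels))
    return Phylogeny(build(shuffled, is_root=True))


@pytest.fixture
def small_bundle():
    """A small but complete synthetic dataset (shared across tests)."""
    scenario = ps.Scenario(n_species=24, total_stems=1500, seed=42)
    return ps.make_scenario_bundle(scenario)
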