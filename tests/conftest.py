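import numpy as np
import pandas as pd
import pytest

import chemosignal as cs


@pytest.fixture
def star_tree():
    """Five tips, equal pendant branches of length 2."""
    return cs.read_newick("(A:2,B:2,C:2,D:2,E:2);")


@pytest.fixture
def balanced_tree():
    """((A:1,B:1):1,(C:1,D:1):1) -- the canonical 4-tip VCV example."""
    return cs.read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def three_taxon_dm():
    """d(A,B)=2, d(A,C)=d(B,C)=4: pendant lengths 1, 1, 3."""
    return cs.DistanceMatrix(
        ("A", "B", "C"), np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
    )


@pytest.fixture
def small_concentration_table():
    """One species, two populations, single compound, young+old strata."""
    rows = []
    for pop, value in (("A", 42.0), ("B", 30.6)):
        for age in ("young", "old"):
            for rep in (1, 2):
                rows.append(("Lepidium draba", pop, age, rep, "gs1", value))
    return pd.DataFrame(
        rows,
        columns=["species", "population", "leaf_age", "replicate",
                 "compound", "concentration_umol_g"],
    )


def random_additive_tree(seed: int, n_min: int = 4, n_max: int = 15):
    """Random tree with jittered (non-ultrametric) branch lengths."""
    rng = np.random.default_rng(seed)
    tree = cs.simulate_tree(int(rng.integers(n_min, n_max)), seed=seed)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(edge.length * rng.uniform(0.5, 1.5) + 0.01)
    return tree
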