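"""Shared fixtures: small hand-traceable trees and synthetic bundles."""

import numpy as np
import pytest

from edgetree import parse_newick, prune_taxa
from edgetree.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture
def basic_tree():
    """((A:1,B:1):1,C:2); — 3 leaves, PD 5, ultrametric at depth 2."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    return parse_newick("(A:2,B:2,C:2);")


@pytest.fixture(scope="session")
def small_dataset():
    """50 species / 8 genera synthetic bundle plus its pruned base tree."""
    cfg = SyntheticConfig(n_species=50, n_genera=8, seed=42)
    tree, table = generate_dataset(cfg)
    missing = set(table.loc[table["sampled"] == 0, "species"])
    base = prune_taxa(tree, missing)
    return cfg, tree, table, base


def random_trees(n_trees, max_leaves, seed):
    """Seeded stream of random Yule trees of 2..max_leaves leaves."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_trees):
        n = int(rng.integers(2, max_leaves + 1))
        cfg = SyntheticConfig(
            n_species=n,
            n_genera=1,
            tree_height=float(rng.uniform(1.0, 500.0)),
            seed=int(rng.integers(2**31)),
        )
        from edgetree.synthetic_data import simulate_tree

        out.append(simulate_tree(cfg))
    return out
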