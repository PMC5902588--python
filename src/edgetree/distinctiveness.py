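"""Phylogenetic diversity and fair-proportion evolutionary distinctiveness.

PD is the total branch length of a rooted tree.  The fair-proportion ED of
a species divides every edge on its root-to-tip path by the number of
leaves descending from that edge, so that the ED values of all species
partition the tree's PD exactly.  ED is computed independently on each
imputation replicate and summarised per species by the median.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import dendropy


def phylogenetic_diversity(tree: dendropy.Tree) -> float:
    """Sum of all edge lengths (root stem excluded)."""
    total = 0.0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        total += node.edge.length or 0.0
    return total


def fair_proportion(tree: dendropy.Tree) -> dict[str, float]:
    """Fair-proportion ED per species, in the tree's branch-length units.

    ED(s) = sum over edges e on the root->s path of len(e) / n_leaves(e).
    Polytomies need no special treatment; the per-edge leaf count is used
    directly.  The values sum to the tree's PD.
    """
    n_leaves: dict[int, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            n_leaves[id(node)] = 1
        else:
            n_leaves[id(node)] = sum(n_leaves[id(c)] for c in node.child_nodes())
    ed: dict[str, float] = {}
    acc: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            share = 0.0
        else:
            share = acc[id(node.parent_node)] + (
                (node.edge.length or 0.0) / n_leaves[id(node)]
            )
            acc[id(node)] = share
        if node.is_leaf():
            ed[node.taxon.label] = share
    return ed


def median_ed(replicates: Sequence[Mapping[str, float]]) -> pd.DataFrame:
    """Aggregate per-replicate ED maps into a per-species table.

    All maps must share an identical species key set.  Returns a DataFrame
    indexed by species with one ``rep_<i>`` column per replicate and a
    ``median_ed`` column (even replicate counts use the mean of the two
    middle order statistics, i.e. the ordinary arithmetic median).
    """
    if not replicates:
        raise ValueError("no replicates supplied")
    key0 = set(replicates[0])
    for i, rep in enumerate(replicates[1:], start=1):
        diff = key0.symmetric_difference(rep)
        if diff:
            raise ValueError(
                f"replicate {i} species set differs from replicate 0: "
                f"{sorted(diff)[:10]}"
            )
    species = sorted(key0)
    mat = np.array([[rep[s] for rep in replicates] for s in species], dtype=float)
    df = pd.DataFrame(
        mat, index=pd.Index(species, name="species"),
        columns=[f"rep_{i}" for i in range(len(replicates))],
    )
    df["median_ed"] = np.median(mat, axis=1)
    return df
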