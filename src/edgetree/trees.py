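"""Rooted ultrametric phylogeny I/O and manipulation.

Trees are held as :class:`dendropy.Tree` objects.  All functions here treat
the tree as rooted; a branch length attached to the root itself (a "root
stem") has no fair-proportion owner set and is ignored for leaf depths and
phylogenetic diversity (a warning is logged when one is encountered).

Newick dialect: underscores in unquoted labels are kept as literal
characters rather than converted to spaces, because species names act as
machine keys joining the tree to the species table.  Quoted labels
(including labels containing spaces) are preserved verbatim.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import dendropy

logger = logging.getLogger(__name__)

DEFAULT_ULTRAMETRIC_RTOL = 1e-6


class NewickParseError(ValueError):
    """Raised when Newick text cannot be interpreted as a valid tree."""


class TreeStructureError(ValueError):
    """Raised when an operation's structural preconditions are violated."""


def _validate_parsed(tree: dendropy.Tree) -> dendropy.Tree:
    seen: set[str] = set()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise NewickParseError("tree contains an unlabeled leaf")
        if leaf.taxon.label in seen:
            raise NewickParseError(f"duplicate leaf label: {leaf.taxon.label!r}")
        seen.add(leaf.taxon.label)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            if node.edge.length is not None:
                logger.warning(
                    "root edge length %s ignored for depths and PD",
                    node.edge.length,
                )
            continue
        if node.edge.length is None:
            label = node.taxon.label if node.taxon else "<internal>"
            raise NewickParseError(f"missing branch length on edge above {label}")
        if node.edge.length < 0:
            label = node.taxon.label if node.taxon else "<internal>"
            raise NewickParseError(
                f"negative branch length {node.edge.length} above {label}"
            )
    return tree


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single rooted Newick statement into a tree.

    Every non-root edge must carry a branch length and leaf labels must be
    unique; violations raise :class:`NewickParseError` identifying the
    offending position or label.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several reader error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return _validate_parsed(tree)


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to Newick with full-precision branch lengths.

    ``parse_newick(write_newick(t))`` reproduces topology, labels and
    lengths exactly; labels with spaces are quoted, labels with
    underscores stay literal.
    """
    return tree.as_string(
        schema="newick",
        preserve_spaces=True,
        suppress_rooting=True,
    )


def read_newick(path) -> dendropy.Tree:
    """Read the first (single) tree from a Newick file."""
    with open(path) as fh:
        return parse_newick(fh.read())


def read_tree_list(path) -> list[dendropy.Tree]:
    """Read an ordered list of trees (e.g. imputation replicates)."""
    try:
        trees = dendropy.TreeList.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise NewickParseError(f"malformed Newick in {path}: {exc}") from exc
    return [_validate_parsed(t) for t in trees]


def write_tree_list(trees: Sequence[dendropy.Tree], path) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(write_newick(tree))


def leaf_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length for every leaf, excluding any root stem."""
    depths: dict[str, float] = {}
    node_depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            d = 0.0
        else:
            d = node_depth[id(node.parent_node)] + (node.edge.length or 0.0)
            node_depth[id(node)] = d
        if node.is_leaf():
            depths[node.taxon.label] = d
    return depths


def node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Depth (distance from root, root stem excluded) of every node."""
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def tree_height(tree: dendropy.Tree) -> float:
    """Maximum leaf depth (the age of the root for an ultrametric tree)."""
    return max(leaf_depths(tree).values())


def is_ultrametric(
    tree: dendropy.Tree, rel_tol: float = DEFAULT_ULTRAMETRIC_RTOL
) -> tuple[bool, float]:
    """Check that all leaves are (nearly) equidistant from the root.

    Returns ``(ok, spread)`` where spread is ``max depth - min depth``;
    the tree passes when spread <= rel_tol * max depth.
    """
    depths = list(leaf_depths(tree).values())
    if not depths:
        raise TreeStructureError("tree has no leaves")
    spread = max(depths) - min(depths)
    limit = rel_tol * max(depths) if max(depths) > 0 else 0.0
    return spread <= limit, spread


def _suppress_unary_nonroot(tree: dendropy.Tree) -> None:
    """Splice out internal nodes with a single child, summing edge lengths.

    A unary root is kept so that pruning never changes retained leaf
    depths.
    """
    for node in list(tree.postorder_node_iter()):
        if node is tree.seed_node or node.is_leaf():
            continue
        children = node.child_nodes()
        if len(children) == 1:
            child = children[0]
            child.edge.length = (child.edge.length or 0.0) + (node.edge.length or 0.0)
            parent = node.parent_node
            parent.remove_child(node)
            node.remove_child(child)
            parent.add_child(child)


def prune_taxa(tree: dendropy.Tree, labels: Iterable[str]) -> dendropy.Tree:
    """Return a copy of the tree with the given leaves removed.

    Unary internal nodes created by pruning are suppressed with their
    incident edge lengths summed, so every retained leaf keeps its original
    depth.  Pruning all leaves or naming an unknown leaf is an error.
    """
    labels = set(labels)
    out = tree.clone(depth=1)
    if not labels:
        return out
    leaf_labels = {lf.taxon.label for lf in out.leaf_node_iter()}
    unknown = labels - leaf_labels
    if unknown:
        raise TreeStructureError(f"unknown leaf labels: {sorted(unknown)}")
    if labels >= leaf_labels:
        raise TreeStructureError("pruning would remove every leaf")
    taxa = [out.taxon_namespace.get_taxon(lab) for lab in sorted(labels)]
    out.prune_taxa(taxa, suppress_unifurcations=False)
    _suppress_unary_nonroot(out)
    return out


def genus_crown(tree: dendropy.Tree, members: Iterable[str]) -> dendropy.Node:
    """Most recent common ancestor of a set of leaves.

    For a single member the leaf itself is returned.
    """
    members = set(members)
    if not members:
        raise TreeStructureError("empty member set")
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    unknown = members - leaves.keys()
    if unknown:
        raise TreeStructureError(f"unknown leaf labels: {sorted(unknown)}")
    if len(members) == 1:
        return leaves[next(iter(members))]
    # walk up from an arbitrary member until the subtree covers all members
    target = frozenset(members)
    node = leaves[next(iter(members))]
    while node.parent_node is not None:
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if target <= below:
            return node
        node = node.parent_node
    return node
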