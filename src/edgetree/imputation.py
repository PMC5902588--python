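"""Random within-genus grafting of species lacking sequence data.

Species without molecular data are attached at random positions inside
their genus on an ultrametric tree, with the new pendant edge sized so the
added leaf reaches the tree height (ultrametricity is preserved).  The
whole set of missing species is grafted repeatedly to produce replicate
trees, so downstream ED values can be summarised over the randomness of
the placements.

Attachment rule: candidate edges are all edges strictly inside the genus
crown clade (pendant and internal); when the genus has exactly one sampled
leaf, that leaf's pendant edge is the single candidate.  The attachment
point is drawn uniformly over the total candidate branch length (so an
edge is chosen with probability proportional to its length, and the height
along it is uniform); the new pendant runs from that point to the height
of the tree.  Within one replicate, grafts are applied sequentially in
plan order, so later congeners may attach to earlier grafts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import dendropy

from edgetree.trees import (
    TreeStructureError,
    genus_crown,
    leaf_depths,
    node_depths,
)


class ImputationError(ValueError):
    """Raised for infeasible or inconsistent imputation plans."""


@dataclass(frozen=True)
class ImputationPlan:
    """Which species to graft, into which genus, how often, and the seed.

    ``genus_members`` maps each genus to the labels of its sampled leaves
    in the base tree.  Every genus referenced by ``missing_species`` must
    have at least one sampled member; a genus with none is a hard error
    because there is no attachment anchor.
    """

    missing_species: tuple[tuple[str, str], ...]
    n_replicates: int
    seed: int
    genus_members: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ImputationError("n_replicates must be >= 1")
        for species, genus in self.missing_species:
            if not self.genus_members.get(genus):
                raise ImputationError(
                    f"genus {genus!r} (for species {species!r}) has no "
                    "sampled member in the base tree"
                )


def plan_from_table(
    table, n_replicates: int, seed: int
) -> ImputationPlan:
    """Build a plan from a species table DataFrame.

    Expects columns ``species``, ``genus`` and ``sampled`` (0/1); rows
    with ``sampled == 0`` define the species to graft, in table order.
    """
    missing = tuple(
        (row.species, row.genus)
        for row in table.itertuples()
        if not int(row.sampled)
    )
    members: dict[str, tuple[str, ...]] = {}
    sampled = table[table["sampled"].astype(int) == 1]
    for genus, grp in sampled.groupby("genus", sort=True):
        members[str(genus)] = tuple(grp["species"])
    return ImputationPlan(
        missing_species=missing,
        n_replicates=n_replicates,
        seed=seed,
        genus_members=members,
    )


def _candidate_edges(
    tree: dendropy.Tree, genus_members: Sequence[str]
) -> list[dendropy.Node]:
    """Nodes whose parent edges may receive the graft, in preorder."""
    crown = genus_crown(tree, genus_members)
    if crown.is_leaf():
        # single sampled member: only its pendant edge is available
        return [crown]
    return [node for node in crown.preorder_iter() if node is not crown]


def _graft_in_place(
    tree: dendropy.Tree,
    species: str,
    genus_members: Sequence[str],
    rng: np.random.Generator,
    target_height: float,
) -> None:
    candidates = _candidate_edges(tree, genus_members)
    lengths = np.array([c.edge.length or 0.0 for c in candidates])
    total = float(lengths.sum())
    if total > 0.0:
        # one uniform draw over the clade's total branch length fixes both
        # the edge (length-weighted) and the height along it
        pos = float(rng.uniform(0.0, total))
        cum = np.cumsum(lengths)
        idx = int(np.searchsorted(cum, pos, side="right"))
        idx = min(idx, len(candidates) - 1)
        u = pos - (float(cum[idx - 1]) if idx else 0.0)
    else:
        idx = int(rng.integers(len(candidates)))
        u = 0.0
    head = candidates[idx]
    parent = head.parent_node
    edge_len = head.edge.length or 0.0
    depths = node_depths(tree)
    top_depth = depths[parent]
    attach_depth = top_depth + u
    pendant = target_height - attach_depth
    if pendant < 0:
        # can only arise from floating-point noise on an ultrametric tree
        pendant = 0.0
    parent.remove_child(head)
    mid = parent.new_child(edge_length=u)
    mid.add_child(head)
    head.edge.length = edge_len - u
    taxon = tree.taxon_namespace.require_taxon(label=species)
    mid.new_child(taxon=taxon, edge_length=pendant)


def graft_species(
    tree: dendropy.Tree,
    species: str,
    genus_members: Iterable[str],
    rng: np.random.Generator,
) -> dendropy.Tree:
    """Return a copy of the tree with one species grafted into its genus.

    The new leaf's depth equals the mean leaf depth of the input tree, so
    an ultrametric input stays ultrametric.  The input tree is unchanged.
    """
    genus_members = sorted(set(genus_members))
    if not genus_members:
        raise ImputationError("empty genus member set")
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if species in labels:
        raise ImputationError(f"species {species!r} is already a leaf")
    missing = set(genus_members) - labels
    if missing:
        raise TreeStructureError(f"genus members not in tree: {sorted(missing)}")
    out = tree.clone(depth=1)
    target = float(np.mean(list(leaf_depths(out).values())))
    _graft_in_place(out, species, genus_members, rng, target)
    return out


def impute_replicates(
    tree: dendropy.Tree, plan: ImputationPlan
) -> list[dendropy.Tree]:
    """Generate ``plan.n_replicates`` trees with all missing species grafted.

    Replicate ``r`` is a pure function of ``(tree, plan.seed, r)``: each
    replicate draws from an independent substream derived from the root
    seed, so replicates are reproducible individually and in order.
    """
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    for species, genus in plan.missing_species:
        if species in labels:
            raise ImputationError(f"species {species!r} is already a leaf")
        absent = set(plan.genus_members[genus]) - labels
        if absent:
            raise ImputationError(
                f"genus {genus!r} members missing from tree: {sorted(absent)}"
            )
    target = float(np.mean(list(leaf_depths(tree).values())))
    replicates = []
    for r in range(plan.n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence((plan.seed, r)))
        rep = tree.clone(depth=1)
        members: dict[str, list[str]] = {
            g: sorted(m) for g, m in plan.genus_members.items()
        }
        for species, genus in plan.missing_species:
            try:
                _graft_in_place(rep, species, members[genus], rng, target)
            except Exception as exc:
                raise ImputationError(
                    f"replicate {r}: failed to graft {species!r} into "
                    f"genus {genus!r}: {exc}"
                ) from exc
            members[genus].append(species)
        replicates.append(rep)
    return replicates
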