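"""NJMerge: Neighbor Joining constrained by trees on disjoint taxon subsets.

The algorithm iterates the NJ agglomeration but screens each siblinghood
proposal (x, y), taken in ascending Q order, against the constraint trees:

Property 1
    If x and y both occur in some constraint tree, they must be siblings
    (a cherry) in it.

Property 2
    Replacing x and y by the merged leaf z in every constraint tree must
    not make any *pair* of constraint trees incompatible.  Each affected
    pair is rooted at z and tested with BUILD.  Because pairwise
    compatibility does not imply joint compatibility of the whole set,
    this heuristic can paint itself into a corner; when no remaining pair
    is acceptable the algorithm raises :class:`NJMergeFailure` rather than
    emit a wrong tree.  The optional ``groupwise`` mode tests all trees
    containing z jointly instead of pairwise.

Whenever NJMerge does return a tree, that tree is a compatibility
supertree for the original forest; this guarantee is asserted internally
before returning (disable with ``verify=False``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from .compat import is_compatibility_supertree, rooted_compatible
from .distances import DistanceMatrix
from .errors import DegenerateInputError, NJMergeFailure, TreeError
from .nj import JoinState
from .tree import PhyloTree, restrict, root_at_leaf

__all__ = [
    "ConstraintForest",
    "MergeResult",
    "check_property1",
    "relabel",
    "check_property2",
    "njmerge",
]


class ConstraintForest:
    """The evolving set of constraint trees plus the leaf-relabeling map.

    Initially the trees' leaf sets are pairwise disjoint; accepted joins
    rename leaves to shared merged labels, so leaf sets may come to
    overlap.  Trees shrunk to <= 2 leaves are dropped (they constrain
    nothing); 3-leaf trees are retained but impose no unrooted topology.
    """

    def __init__(self, trees: Sequence[PhyloTree]):
        seen: set[str] = set()
        for t in trees:
            if t.rooted:
                raise TreeError("constraint trees must be unrooted")
            if not t.is_binary():
                raise TreeError("constraint trees must be binary")
            overlap = seen & t.leaf_labels()
            if overlap:
                raise TreeError(
                    f"constraint leaf sets are not pairwise disjoint: {sorted(overlap)}"
                )
            seen |= t.leaf_labels()
        self.trees: list[PhyloTree] = [t.copy() for t in trees]
        # registry: active label -> set of original taxa it represents
        self.registry: dict[str, frozenset[str]] = {
            label: frozenset([label]) for label in seen
        }

    def trees_containing(self, label: str) -> list[int]:
        return [i for i, t in enumerate(self.trees) if label in t.leaf_labels()]

    def copy_subset(self, indices: Sequence[int]) -> list[PhyloTree]:
        return [self.trees[i].copy() for i in indices]


def check_property1(forest: ConstraintForest, x: str, y: str) -> bool:
    """Siblinghood screen: in every constraint tree containing both x and
    y, the pair must form a cherry.  Vacuously true when no tree contains
    both; trees on <= 3 leaves impose nothing (their unrooted topology is
    unique, so any pair may be joined)."""
    for tree in forest.trees:
        leaves = tree.leaf_labels()
        if x in leaves and y in leaves:
            if len(leaves) <= 3:
                continue
            if not tree.has_cherry(x, y):
                return False
    return True


def _relabel_tree(tree: PhyloTree, x: str, y: str, z: str) -> Optional[PhyloTree]:
    """Apply the join (x, y) -> z to one tree; returns None when the tree
    shrinks to <= 2 leaves (dropped)."""
    leaves = tree.leaf_labels()
    has_x, has_y = x in leaves, y in leaves
    if not has_x and not has_y:
        return tree
    if has_x and has_y:
        # cherry (x, y) contracts to the single leaf z: pruning one member
        # and renaming the other is the same operation
        if len(leaves) <= 3:
            return None
        new = restrict(tree, leaves - {x})
        new.find_leaf(y).label = z
        return new
    new = tree.copy()
    new.find_leaf(x if has_x else y).label = z
    return new


def relabel(forest: ConstraintForest, x: str, y: str, z: str) -> None:
    """Update the forest in place for the accepted join z = (x, y).

    A tree containing exactly one of x, y has that leaf renamed z; a tree
    containing both (necessarily as a cherry, by Property 1) has the
    cherry contracted to the single leaf z; trees falling to <= 2 leaves
    are dropped."""
    updated: list[PhyloTree] = []
    for tree in forest.trees:
        new = _relabel_tree(tree, x, y, z)
        if new is not None and len(new) >= 3:
            updated.append(new)
    forest.trees = updated
    merged = forest.registry.pop(x, frozenset([x])) | forest.registry.pop(
        y, frozenset([y])
    )
    forest.registry[z] = merged


def check_property2(
    forest: ConstraintForest,
    x: str,
    y: str,
    z: str,
    mode: Literal["pairwise", "groupwise"] = "pairwise",
) -> bool:
    """Compatibility screen for the proposal z = (x, y).

    Simulates the relabeling on copies, gathers the updated trees that
    contain z, roots each at z, and tests rooted compatibility — for every
    unordered pair in ``pairwise`` mode, or for the whole group at once in
    ``groupwise`` mode.  Only trees containing x or y need checking; all
    other pairs are untouched by the join."""
    affected = sorted(set(forest.trees_containing(x)) | set(forest.trees_containing(y)))
    updated: list[PhyloTree] = []
    for i in affected:
        new = _relabel_tree(forest.trees[i].copy(), x, y, z)
        if new is not None and len(new) >= 4 and z in new.leaf_labels():
            updated.append(new)
    if len(updated) <= 1:
        return True
    rooted = [root_at_leaf(t, z) for t in updated]
    if mode == "groupwise":
        return rooted_compatible(rooted)
    from itertools import combinations

    return all(rooted_compatible([a, b]) for a, b in combinations(rooted, 2))


@dataclass
class MergeResult:
    """Outcome of a successful merge."""

    tree: PhyloTree
    join_log: list[tuple[str, str, str]] = field(default_factory=list)
    proposal_ranks: list[int] = field(default_factory=list)


def njmerge(
    forest: Sequence[PhyloTree],
    D: DistanceMatrix,
    mode: Literal["pairwise", "groupwise"] = "pairwise",
    verify: bool = True,
) -> MergeResult:
    """Merge constraint trees on pairwise disjoint leaf sets into a single
    unrooted binary tree on the label set of ``D``.

    Parameters
    ----------
    forest:
        Unrooted binary constraint trees on pairwise disjoint subsets of
        the matrix labels.  An empty forest reduces NJMerge to plain NJ.
    D:
        Dissimilarity matrix guiding the joins.
    mode:
        ``pairwise`` (the default heuristic) tests compatibility of
        updated constraint trees pair by pair; ``groupwise`` tests the
        whole set of trees containing the merged leaf at once.
    verify:
        Assert the compatibility-supertree guarantee on the output before
        returning (cheap for the sizes this package targets).

    Raises
    ------
    NJMergeFailure
        When a full scan of the remaining pairs finds no acceptable
        proposal.  The exception carries the join log.
    """
    if len(D) < 3:
        raise DegenerateInputError("NJMerge requires at least 3 taxa")
    original = [t.copy() for t in forest]
    missing = sorted(
        set().union(*(t.leaf_labels() for t in original)) - set(D.labels)
        if original
        else set()
    )
    if missing:
        raise TreeError(f"constraint leaves missing from the matrix: {missing}")
    state = JoinState(D)
    constraints = ConstraintForest(original)
    ranks: list[int] = []
    while state.r > 3:
        accepted = False
        for rank, (x, y) in enumerate(state.sorted_proposals()):
            if not check_property1(constraints, x, y):
                continue
            z = state.fresh_label()
            if not check_property2(constraints, x, y, z, mode=mode):
                continue
            state.join(x, y, z)
            relabel(constraints, x, y, z)
            ranks.append(rank)
            accepted = True
            break
        if not accepted:
            raise NJMergeFailure(
                "no remaining siblinghood proposal preserves pairwise "
                "compatibility of the constraint trees",
                join_log=state.join_log,
            )
    tree = state.close()
    if verify and not is_compatibility_supertree(tree, original):
        raise AssertionError(
            "internal error: output is not a compatibility supertree"
        )
    return MergeResult(tree=tree, join_log=list(state.join_log), proposal_ranks=ranks)
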