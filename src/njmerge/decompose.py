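"""Centroid-edge decomposition of a tree into disjoint taxon subsets.

Used to produce the pairwise disjoint subsets on which subset trees are
built: recursively delete the centroid edge — the edge minimizing the
larger side of its leaf bipartition — until every part fits the size
bound.  Ties are broken deterministically (smallest lexicographic leaf on
the smaller side), so identical input yields identical decompositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DegenerateInputError, TreeError
from .tree import PhyloTree, restrict

__all__ = ["Decomposition", "centroid_decompose"]


@dataclass
class Decomposition:
    """A partition of a taxon set into disjoint subsets under a size bound."""

    subsets: list[frozenset[str]]
    max_size: int
    source: str = ""

    def __post_init__(self):
        union: set[str] = set()
        for s in self.subsets:
            if not s:
                raise TreeError("empty subset in decomposition")
            if union & s:
                raise TreeError("decomposition subsets overlap")
            if len(s) > self.max_size:
                raise TreeError("subset exceeds max_size")
            union |= s
        self.universe = frozenset(union)

    def __len__(self) -> int:
        return len(self.subsets)


def _centroid_edge(tree: PhyloTree) -> frozenset[str]:
    """Leaf set on one side of the centroid edge (the smaller side; ties
    broken by the smallest lexicographic leaf on that side)."""
    n = len(tree)
    best = None
    best_key = None
    for below in tree.clusters():
        if len(below) == 0 or len(below) == n:
            continue
        side_small = below if len(below) <= n - len(below) else tree.leaf_labels() - below
        key = (max(len(below), n - len(below)), min(side_small))
        if best_key is None or key < best_key:
            best_key = key
            best = side_small
    assert best is not None
    return frozenset(best)


def centroid_decompose(tree: PhyloTree, max_size: int) -> Decomposition:
    """Recursively split ``tree`` at centroid edges until every subset has
    at most ``max_size`` leaves.

    Each recursion operates on the restricted trees (degree-2 nodes
    suppressed), so centroid choices stay well-defined.  The result is a
    partition: disjoint, covering, every part nonempty and within bound.
    """
    if max_size < 3:
        raise DegenerateInputError("max_size must be >= 3 for informative subsets")
    if not tree.is_binary():
        raise TreeError("centroid decomposition expects a binary tree")

    parts: list[frozenset[str]] = []

    def split(t: PhyloTree) -> None:
        leaves = t.leaf_labels()
        if len(leaves) <= max_size:
            parts.append(frozenset(leaves))
            return
        side = _centroid_edge(t)
        split(restrict(t, side))
        split(restrict(t, leaves - side))

    split(tree)
    return Decomposition(subsets=parts, max_size=max_size, source="centroid")
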