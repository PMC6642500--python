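"""Agreement testing, supertree compatibility, and the RF metric.

A small tree *agrees with* a big tree when restricting the big tree to the
small tree's leaves (and suppressing degree-2 nodes) gives an isomorphic
tree.  A *compatibility supertree* for a forest is a tree on the full taxon
set that every forest tree agrees with; the forest trees need not form
clades in it.

Rooted-tree compatibility is decided with the classic BUILD recursion of
Aho et al.: partition the leaves by the connectivity graph induced by the
rooted triplets at each level and fail when a level with >= 3 leaves cannot
be split.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

from .errors import TreeError
from .tree import Node, PhyloTree, restrict

__all__ = [
    "bipartition_set",
    "rooted_triplets",
    "agrees_with",
    "is_compatibility_supertree",
    "rooted_compatible",
    "rf_error",
    "clade_join_supertree",
]


def bipartition_set(tree: PhyloTree) -> set[frozenset[frozenset[str]]]:
    """Nontrivial splits of ``tree`` (see :meth:`PhyloTree.bipartitions`)."""
    return tree.bipartitions()


def rooted_triplets(tree: PhyloTree) -> set[tuple[frozenset[str], str]]:
    """All resolved rooted triplets ab|c displayed by a rooted tree.

    A triplet is encoded as ``(frozenset({a, b}), c)`` meaning a and b have
    a strictly deeper common ancestor than either has with c.
    """
    if not tree.rooted:
        raise TreeError("rooted_triplets requires a rooted tree")
    triplets: set[tuple[frozenset[str], str]] = set()
    all_leaves = tree.leaf_labels()

    def below(node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.label])
        kids = [below(c) for c in node.children]
        merged = frozenset().union(*kids)
        outside = all_leaves - merged
        for s1, s2 in combinations(kids, 2):
            for a in s1:
                for b in s2:
                    for c in outside:
                        triplets.add((frozenset([a, b]), c))
        return merged

    below(tree.root)
    return triplets


def agrees_with(small: PhyloTree, big: PhyloTree) -> bool:
    """Definition of agreement: ``restrict(big, leaves(small))`` ~ ``small``."""
    sub = small.leaf_labels()
    if not sub <= big.leaf_labels():
        raise TreeError("small tree's leaves are not a subset of the big tree's")
    if not small.is_binary():
        raise TreeError("agreement is defined for binary constraint trees")
    if len(sub) <= 3:
        return True  # a binary unrooted tree on <= 3 leaves is unique
    induced = restrict(big, sub)
    return induced.is_isomorphic_unrooted(small)


def is_compatibility_supertree(
    candidate: PhyloTree, forest: Sequence[PhyloTree]
) -> bool:
    """True iff every tree of ``forest`` agrees with ``candidate``."""
    return all(agrees_with(t, candidate) for t in forest)


def rooted_compatible(trees: Sequence[PhyloTree]) -> bool:
    """Decide whether a rooted tree exists displaying every input tree.

    Uses BUILD on the union of the trees' rooted triplets.  Trees on <= 2
    leaves carry no topology and are ignored; an empty input is vacuously
    compatible.
    """
    triplets: set[tuple[frozenset[str], str]] = set()
    universe: set[str] = set()
    for t in trees:
        if not t.rooted:
            raise TreeError("rooted_compatible requires rooted trees")
        universe |= t.leaf_labels()
        if len(t) >= 3:
            triplets |= rooted_triplets(t)
    return _build_ok(frozenset(universe), triplets)


def _build_ok(
    leaves: frozenset[str], triplets: set[tuple[frozenset[str], str]]
) -> bool:
    if len(leaves) <= 2:
        return True
    # connectivity graph: join a,b for every triplet ab|c fully inside `leaves`
    parent = {x: x for x in leaves}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    active = []
    for pair, c in triplets:
        if c in leaves and pair <= leaves:
            a, b = sorted(pair)
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
            active.append((pair, c))
    comps: dict[str, set[str]] = {}
    for x in sorted(leaves):
        comps.setdefault(find(x), set()).add(x)
    if len(comps) == 1:
        return False  # this level cannot be split: incompatible
    for comp in comps.values():
        if not _build_ok(frozenset(comp), {t for t in active if t[0] <= comp}):
            return False
    return True


def rf_error(true_tree: PhyloTree, est_tree: PhyloTree) -> float:
    """Normalized Robinson-Foulds error: the proportion of the true tree's
    internal bipartitions missing from the estimated tree.

    Equals the normalized symmetric difference when both trees are binary.
    """
    lt, le = true_tree.leaf_labels(), est_tree.leaf_labels()
    if lt != le:
        raise TreeError("trees must share a leaf set for RF comparison")
    n = len(lt)
    if n < 4:
        raise TreeError("RF error requires >= 4 leaves")
    true_splits = true_tree.bipartitions()
    est_splits = est_tree.bipartitions()
    return len(true_splits - est_splits) / (n - 3)


def clade_join_supertree(forest: Sequence[PhyloTree]) -> PhyloTree:
    """A compatibility supertree for trees on pairwise disjoint leaf sets,
    obtained by hanging each constraint tree off a backbone as a clade.

    Exists for every disjoint forest; used as a constructive witness in
    tests and by the failure-contrast fixtures.
    """
    seen: set[str] = set()
    for t in forest:
        if seen & t.leaf_labels():
            raise TreeError("forest leaf sets are not pairwise disjoint")
        seen |= t.leaf_labels()
    if len(forest) == 0:
        raise TreeError("empty forest")

    def as_subtree(t: PhyloTree) -> Node:
        return t.copy().root

    if len(forest) == 1:
        return forest[0].copy()
    root = Node()
    cur = root
    parts = [as_subtree(t) for t in forest]
    cur.add_child(parts[0])
    for part in parts[1:-1]:
        nxt = Node()
        cur.add_child(nxt)
        nxt.add_child(part)
        cur = nxt
    cur.add_child(parts[-1])
    out = PhyloTree(root, rooted=False)
    return out
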