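"""Shared fixtures and independent oracles for the test suite.

The oracles here (brute-force quartet display, exhaustive rooted-supertree
enumeration, naive path walking) are deliberately written without reusing
the package's traversal code, so they can certify it.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from njmerge import DistanceMatrix, PhyloTree, parse_newick


@pytest.fixture
def caterpillar() -> PhyloTree:
    """The caterpillar on {A..H}: a path with the leaves hanging off it in
    alphabetical order."""
    return parse_newick("(A,(B,(C,(D,(E,(F,(G,H)))))));")


@pytest.fixture
def balanced8() -> PhyloTree:
    return parse_newick("(((A,B),(C,D)),((E,F),(G,H)));")


def make_noise_matrix(n: int, rng: np.random.Generator, labels=None):
    labels = labels or [f"t{i:02d}" for i in range(n)]
    V = rng.uniform(0.5, 2.0, (n, n))
    V = 0.5 * (V + V.T)
    np.fill_diagonal(V, 0.0)
    return DistanceMatrix(labels, V)


# -- rooted-tree enumeration oracle ----------------------------------------


def all_rooted_shapes(labels: tuple[str, ...]):
    """Every rooted binary tree shape on `labels`, as nested tuples."""
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    for shape in all_rooted_shapes(rest):
        yield from _insert_everywhere(shape, first)


def _insert_everywhere(shape, leaf):
    yield (leaf, shape)
    if isinstance(shape, tuple):
        left, right = shape
        for new_left in _insert_everywhere(left, leaf):
            yield (new_left, right)
        for new_right in _insert_everywhere(right, leaf):
            yield (left, new_right)


def shape_to_newick(shape) -> str:
    def fmt(s):
        if isinstance(s, tuple):
            return "(" + ",".join(fmt(x) for x in s) + ")"
        return s

    return fmt(shape) + ";"


def shape_clusters(shape) -> set[frozenset[str]]:
    out = set()

    def walk(s) -> frozenset[str]:
        if not isinstance(s, tuple):
            below = frozenset([s])
        else:
            below = walk(s[0]) | walk(s[1])
        out.add(below)
        return below

    walk(shape)
    return out


def shape_displays(shape, small_clusters: set[frozenset[str]],
                   small_leaves: frozenset[str]) -> bool:
    """Does the rooted shape, restricted to ``small_leaves``, induce exactly
    the clusters of the small (binary) tree?"""
    induced = {
        c & small_leaves
        for c in shape_clusters(shape)
        if len(c & small_leaves) >= 1
    }
    wanted = {c for c in small_clusters if len(c) >= 1}
    return wanted <= induced


def exhaustive_rooted_compatible(trees: list[PhyloTree]) -> bool:
    """Ground truth for rooted compatibility: try every rooted binary tree
    on the union of leaf sets."""
    universe = tuple(sorted(set().union(*(t.leaf_labels() for t in trees))))
    wanted = [(t.clusters() | {t.leaf_labels()}, t.leaf_labels()) for t in trees]
    for shape in all_rooted_shapes(universe):
        if all(shape_displays(shape, cl, lv) for cl, lv in wanted):
            return True
    return False


# -- path-walk oracle -------------------------------------------------------


def tree_adjacency(tree: PhyloTree):
    """Adjacency map over node ids, plus label lookup, built independently
    of the package's traversal helpers."""
    adj: dict[int, list[int]] = {}
    label_of: dict[int, str] = {}
    lengths: dict[tuple[int, int], float] = {}

    def walk(node):
        nid = id(node)
        adj.setdefault(nid, [])
        if node.is_leaf:
            label_of[nid] = node.label
        for child in node.children:
            cid = id(child)
            adj[nid].append(cid)
            adj.setdefault(cid, []).append(nid)
            lengths[(nid, cid)] = lengths[(cid, nid)] = child.length or 0.0
            walk(child)

    walk(tree.root)
    return adj, label_of, lengths


def path_internode_count(tree: PhyloTree, a: str, b: str) -> int:
    """Number of internal nodes on the a-b path, by breadth-first walk."""
    adj, label_of, _ = tree_adjacency(tree)
    start = next(k for k, v in label_of.items() if v == a)
    goal = next(k for k, v in label_of.items() if v == b)
    prev = {start: None}
    queue = [start]
    while queue:
        cur = queue.pop(0)
        if cur == goal:
            break
        for nxt in adj[cur]:
            if nxt not in prev:
                prev[nxt] = cur
                queue.append(nxt)
    count = 0
    cur = prev[goal]
    while cur is not None and cur != start:
        if cur not in label_of:
            count += 1
        cur = prev[cur]
    return count


def quartet_topology_bruteforce(tree: PhyloTree, four: tuple[str, str, str, str]):
    """Which of the three quartet topologies does ``tree`` display on the
    four given leaves?  Decided by path lengths in edge counts: the pair
    partition minimizing the sum of within-pair distances wins."""
    adj, label_of, _ = tree_adjacency(tree)
    ids = {v: k for k, v in label_of.items()}

    def hops(a, b):
        start, goal = ids[a], ids[b]
        dist = {start: 0}
        queue = [start]
        while queue:
            cur = queue.pop(0)
            if cur == goal:
                return dist[cur]
            for nxt in adj[cur]:
                if nxt not in dist:
                    dist[nxt] = dist[cur] + 1
                    queue.append(nxt)
        raise AssertionError("disconnected tree")

    a, b, c, d = four
    options = {
        frozenset([frozenset([a, b]), frozenset([c, d])]): hops(a, b) + hops(c, d),
        frozenset([frozenset([a, c]), frozenset([b, d])]): hops(a, c) + hops(b, d),
        frozenset([frozenset([a, d]), frozenset([b, c])]): hops(a, d) + hops(b, c),
    }
    best = min(options.values())
    winners = [k for k, v in options.items() if v == best]
    return winners[0] if len(winners) == 1 else None  # None: unresolved/star
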