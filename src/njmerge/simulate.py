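"""Hermetic simulation fixtures: random trees, Yule species trees, MSC gene
trees, Jukes-Cantor sequences, nearly-additive matrices, and adversarial
(failure-inducing) constraint forests.

These generators define the study conditions the rest of the package is
tested under.  All of them are seed-deterministic.

Conventions
-----------
* Species-tree branch lengths are in generations; coalescent units are
  generations divided by the (haploid-equivalent) effective population
  size N.  The default N is 200,000.
* Gene trees are simulated with msprime (one haploid lineage per species,
  free coalescence above the root).
* Sequences evolve under Jukes-Cantor with branch lengths in expected
  substitutions per site, i.i.d. sites, no indels.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .distances import DistanceMatrix
from .errors import DegenerateInputError, NJMergeError, NJMergeFailure, TreeError
from .tree import Alignment, Node, PhyloTree, restrict, write_newick

__all__ = [
    "MSCModel",
    "random_binary_tree",
    "yule_species_tree",
    "msc_gene_trees",
    "jc_sequences",
    "nearly_additive_perturb",
    "adversarial_forest",
]

DEFAULT_POP_SIZE = 200_000.0


def _default_labels(n: int) -> list[str]:
    width = len(str(n))
    return [f"t{str(i + 1).zfill(width)}" for i in range(n)]


def random_binary_tree(
    n: int,
    seed: int,
    labels: Optional[Sequence[str]] = None,
    rooted: bool = False,
    min_length: float = 0.05,
    max_length: float = 1.0,
) -> PhyloTree:
    """A uniformly random binary topology on ``n`` labelled leaves, grown by
    attaching each new leaf to a uniformly chosen edge; branch lengths are
    log-uniform on [min_length, max_length]."""
    if n < 3:
        raise DegenerateInputError("random trees require n >= 3")
    labels = list(labels) if labels is not None else _default_labels(n)
    if len(labels) != n:
        raise TreeError(f"need {n} labels, got {len(labels)}")
    rng = np.random.default_rng(seed)
    root = Node()
    for lab in labels[:3]:
        root.add_child(Node(lab))
    nodes = list(root.children)  # non-root nodes, one per edge
    for lab in labels[3:]:
        target = nodes[int(rng.integers(len(nodes)))]
        parent = target.parent
        mid = Node()
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add_child(target)
        leaf = Node(lab)
        mid.add_child(leaf)
        nodes.extend([mid, leaf])
    tree = PhyloTree(root, rooted=False)
    for node in tree.iter_nodes():
        if node.parent is not None:
            node.length = float(
                np.exp(rng.uniform(np.log(min_length), np.log(max_length)))
            )
    if rooted:
        # root along a uniformly chosen edge by subdividing it
        edges = [nd for nd in tree.iter_nodes() if nd.parent is not None]
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent
        new_root = Node()
        parent.children.remove(target)
        half = (target.length or 0.0) / 2.0
        target.length = half
        new_root.add_child(target)
        sib = _reorient(parent)  # the rest of the tree, hung from the edge's far end
        sib.length = half
        new_root.add_child(sib)
        return PhyloTree(new_root, rooted=True)
    return tree


def _reorient(node: Node) -> Node:
    """Make ``node`` the top of its component by flipping parent edges."""
    path = []
    cur = node
    while cur is not None:
        path.append(cur)
        cur = cur.parent
    orig_lengths = [nd.length for nd in path]
    for i in range(len(path) - 1):
        child, parent = path[i], path[i + 1]
        if child in parent.children:
            parent.children.remove(child)
        child.children.append(parent)
        parent.parent = child
        parent.length = orig_lengths[i]
    node.parent = None
    node.length = None
    return node


def yule_species_tree(
    n: int, height_gens: float, seed: int, labels: Optional[Sequence[str]] = None
) -> PhyloTree:
    """A pure-birth (Yule) species tree on ``n`` taxa, rescaled so the root
    height equals ``height_gens`` generations.  Branch lengths are in
    generations, as required by the coalescent simulator."""
    import dendropy
    from dendropy.model import birthdeath

    if n < 2:
        raise DegenerateInputError("need n >= 2 species")
    rng = random.Random(seed)
    dtree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n,
        rng=rng,
    )
    dtree.seed_node.edge.length = None
    text = dtree.as_string(schema="newick", suppress_rooting=True)
    from .tree import parse_newick

    tree = parse_newick(text.strip(), rooted=True)
    # the simulator stops at the n-th birth, leaving the newest tips with
    # zero-length pendant edges; run the clock one more exponential waiting
    # time so every pendant edge is positive (ultrametry is preserved)
    extra = rng.expovariate(n * 1.0)
    for leaf in tree.iter_leaves():
        leaf.length = (leaf.length or 0.0) + extra
    # rescale to the requested height
    def depth(node: Node) -> float:
        if node.is_leaf:
            return 0.0
        return max((c.length or 0.0) + depth(c) for c in node.children)

    h = depth(tree.root)
    scale = height_gens / h
    for node in tree.iter_nodes():
        if node.length is not None:
            node.length *= scale
    # snap to exact ultrametry (the coalescent simulator requires all leaf
    # times to coincide to machine precision)
    def leaf_depths(node: Node, acc: float, out: dict) -> None:
        acc += node.length or 0.0
        if node.is_leaf:
            out[node.label] = (node, acc)
        for c in node.children:
            leaf_depths(c, acc, out)

    depths: dict[str, tuple[Node, float]] = {}
    leaf_depths(tree.root, 0.0, depths)
    top = max(d for _, d in depths.values())
    for leaf, d in depths.values():
        leaf.length = (leaf.length or 0.0) + (top - d)
    if labels is not None:
        if len(labels) != n:
            raise TreeError(f"need {n} labels, got {len(labels)}")
        for leaf, lab in zip(sorted(tree.iter_leaves(), key=lambda l: l.label), labels):
            leaf.label = lab
    return tree


@dataclass
class MSCModel:
    """A multispecies-coalescent model: a rooted species tree with branch
    lengths in generations, and a haploid-equivalent effective population
    size shared by all branches."""

    species_tree: PhyloTree
    pop_size: float = DEFAULT_POP_SIZE

    def __post_init__(self):
        if self.pop_size <= 0:
            raise NJMergeError("population size must be positive")
        if not self.species_tree.rooted:
            raise TreeError("MSC model requires a rooted species tree")
        for node in self.species_tree.iter_nodes():
            if node.parent is not None and (node.length is None or node.length <= 0):
                raise TreeError("species tree needs positive branch lengths")


def _tskit_to_phylo(ts, names: dict[int, str]) -> PhyloTree:
    t = ts.first()

    def conv(u: int) -> Node:
        kids = t.children(u)
        if not kids:
            node = Node(names[u])
        else:
            node = Node()
            for k in kids:
                node.add_child(conv(k))
        node.length = t.branch_length(u) or None
        return node

    root = conv(t.root)
    root.length = None
    return PhyloTree(root, rooted=True)


def msc_gene_trees(model: MSCModel, count: int, seed: int) -> list[PhyloTree]:
    """Simulate ``count`` gene trees under the multispecies coalescent with
    one haploid lineage sampled per species.

    Coalescence within each species-tree branch happens at pairwise rate
    1/N per generation (ploidy 1), so a branch of g generations spans
    g / N coalescent units; lineages reaching the species-tree root
    coalesce freely above it.
    """
    import msprime

    if count < 1:
        raise NJMergeError("count must be >= 1")
    newick = write_newick(model.species_tree, with_lengths=True)
    demography = msprime.Demography.from_species_tree(
        newick, initial_size=model.pop_size
    )
    species = sorted(model.species_tree.leaf_labels())
    replicates = msprime.sim_ancestry(
        samples={s: 1 for s in species},
        demography=demography,
        ploidy=1,
        random_seed=int(seed) % (2**31 - 1) + 1,
        num_replicates=count,
    )
    pop_names: dict[int, str] = {}
    out = []
    for ts in replicates:
        if not pop_names:
            for pop in ts.populations():
                meta = pop.metadata
                name = meta.get("name") if isinstance(meta, dict) else None
                pop_names[pop.id] = name or f"pop_{pop.id}"
        names = {u: pop_names[ts.node(u).population] for u in ts.samples()}
        out.append(_tskit_to_phylo(ts, names))
    return out


_JC_BASES = np.arange(4)


def jc_sequences(tree: PhyloTree, length: int, seed: int) -> Alignment:
    """Evolve i.i.d. sites down ``tree`` under the Jukes-Cantor model.

    Branch lengths are expected substitutions per site; each site changes
    along a branch of length t with probability (3/4)(1 - e^{-4t/3}), to a
    uniformly chosen different base.  No insertions or deletions.
    """
    if length < 1:
        raise NJMergeError("alignment length must be >= 1")
    for node in tree.iter_nodes():
        if node.parent is not None and node.length is None:
            raise TreeError("JC simulation requires branch lengths on every edge")
    rng = np.random.default_rng(seed)
    records: dict[str, str] = {}
    alphabet = np.array(list("ACGT"))

    def evolve(node: Node, state: np.ndarray) -> None:
        if node.parent is not None:
            t = node.length or 0.0
            p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
            hit = rng.random(length) < p_change
            if hit.any():
                state = state.copy()
                # shift by 1..3 mod 4: uniform over the three other bases
                state[hit] = (state[hit] + rng.integers(1, 4, hit.sum())) % 4
        if node.is_leaf:
            records[node.label] = "".join(alphabet[state])
        else:
            for child in node.children:
                evolve(child, state)

    root_state = rng.integers(0, 4, length)
    evolve(tree.root, root_state)
    return Alignment(records)


def nearly_additive_perturb(
    D: DistanceMatrix, tree: PhyloTree, seed: int, scale: float = 0.49
) -> DistanceMatrix:
    """Perturb an additive matrix within the nearly-additive envelope: every
    off-diagonal entry moves by less than half the shortest branch length
    of the generating tree (default 0.49x), preserving symmetry.

    Matrices in this envelope are exactly the regime in which NJ — and
    NJMerge with agreeing constraints — provably recover the tree.
    """
    if not 0 <= scale < 0.5:
        raise NJMergeError("scale must lie in [0, 0.5) to stay nearly additive")
    shortest = min(
        node.length for node in tree.iter_nodes() if node.parent is not None
    )
    eps = scale * shortest
    rng = np.random.default_rng(seed)
    n = len(D)
    noise = rng.uniform(-eps, eps, size=(n, n))
    noise = np.triu(noise, k=1)
    noise = noise + noise.T
    return DistanceMatrix(D.labels, np.maximum(D.values + noise, 0.0))


def adversarial_forest(
    seed: int,
    max_taxa: int = 12,
    budget: int = 500,
) -> tuple[list[PhyloTree], DistanceMatrix]:
    """Search for a disjoint constraint forest plus matrix on which the
    pairwise-compatibility heuristic fails.

    The matrix is pure symmetric noise (no generating tree) and each
    constraint tree is the restriction of its own independent random tree,
    so early greedy joins can strand the merge in a state where no
    remaining pair is acceptable.  Each candidate instance is certified by
    actually running the merger; the first failing one is returned.
    Raises :class:`NJMergeError` when the budget is exhausted (regenerate
    with another seed).
    """
    from .merge import njmerge

    rng = np.random.default_rng(seed)
    for _attempt in range(budget):
        n = int(rng.integers(10, max_taxa + 1))
        labels = _default_labels(n)
        V = rng.uniform(0.5, 2.0, (n, n))
        V = 0.5 * (V + V.T)
        np.fill_diagonal(V, 0.0)
        D = DistanceMatrix(labels, V)
        shuffled = list(labels)
        rng.shuffle(shuffled)
        k = int(rng.integers(2, 4))
        sizes = np.full(k, n // k)
        sizes[: n % k] += 1
        parts, prev = [], 0
        for s in sizes:
            parts.append(frozenset(shuffled[prev : prev + int(s)]))
            prev += int(s)
        parts = [p for p in parts if len(p) >= 4]
        if len(parts) < 2:
            continue
        forest = []
        for p in parts:
            conflict = random_binary_tree(
                n, int(rng.integers(2**31 - 1)), labels=labels
            )
            forest.append(restrict(conflict, p))
        try:
            njmerge(forest, D, verify=False)
        except NJMergeFailure:
            return forest, D
        except NJMergeError:
            continue
    raise NJMergeError(
        f"no failure-inducing instance found within {budget} attempts; "
        "try another seed"
    )
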