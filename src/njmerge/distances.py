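"""Distance matrices: the labelled container, PHYLIP I/O, and the three
matrix constructions used by the pipeline and its tests.

* ``agid_matrix`` — average gene-tree internode distance (the NJst matrix):
  for each pair of taxa, the mean over gene trees containing both of the
  number of internal nodes on the path between them.
* ``logdet_matrix`` — paralinear (log-det) distances from an alignment,
  consistent under general Markov substitution models.
* ``additive_matrix`` — pairwise path lengths of an edge-weighted tree
  (the test oracle: satisfies the four-point condition).

Entries are dissimilarities: symmetry and a zero diagonal are enforced,
the triangle inequality is not assumed.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np

from .errors import MatrixError, SaturationError, TreeError
from .tree import Alignment, Node, PhyloTree

__all__ = [
    "DistanceMatrix",
    "agid_matrix",
    "logdet_matrix",
    "additive_matrix",
    "read_matrix",
    "write_matrix",
]

_NUC = {"A": 0, "C": 1, "G": 2, "T": 3}


class DistanceMatrix:
    """A symmetric labelled dissimilarity matrix with zero diagonal."""

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        labels = list(labels)
        values = np.asarray(values, dtype=float)
        n = len(labels)
        if len(set(labels)) != n:
            raise MatrixError("duplicate labels")
        if values.shape != (n, n):
            raise MatrixError(f"matrix shape {values.shape} != ({n}, {n})")
        if not np.allclose(values, values.T, atol=1e-6):
            raise MatrixError("matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-9):
            raise MatrixError("matrix diagonal is not zero")
        if np.any(values < -1e-12):
            raise MatrixError("negative dissimilarity")
        self.labels = labels
        self.values = 0.5 * (values + values.T)
        np.fill_diagonal(self.values, 0.0)
        self._index = {lab: i for i, lab in enumerate(labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        labels = list(labels)
        missing = [l for l in labels if l not in self._index]
        if missing:
            raise MatrixError(f"labels not in matrix: {missing}")
        idx = [self._index[l] for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DistanceMatrix n={len(self)}>"


# -- AGID -------------------------------------------------------------------


def _internode_counts(tree: PhyloTree) -> dict[frozenset[str], int]:
    """Number of internal nodes on the path between every leaf pair."""
    # depth in "internal nodes passed, inclusive of endpoints' ancestors":
    # path internode count = depth(a) + depth(b) - 2*depth(lca) + 1 where
    # depth counts internal nodes above the leaf up to the root.  Implemented
    # directly by post-order merging of leaf lists with node distances.
    out: dict[frozenset[str], int] = {}

    def walk(node: Node) -> list[tuple[str, int]]:
        # returns (leaf, #internal nodes strictly between leaf and node,
        # counting node itself if node is internal)
        if node.is_leaf:
            return [(node.label, 0)]
        groups = [walk(c) for c in node.children]
        for gi, gj in combinations(groups, 2):
            for a, da in gi:
                for b, db in gj:
                    out[frozenset((a, b))] = da + db + 1
        merged = [(leaf, d + 1) for g in groups for (leaf, d) in g]
        return merged

    walk(tree.root)
    return out


def agid_matrix(gene_trees: Sequence[PhyloTree]) -> DistanceMatrix:
    """Average gene-tree internode distance matrix.

    Entry (i, j) is the mean, over gene trees containing both i and j, of
    the internode distance (number of internal nodes on the i-j path).
    Taxa missing from some gene trees are averaged over the co-occurring
    ones; a pair that never co-occurs is an error.
    """
    if not gene_trees:
        raise MatrixError("need at least one gene tree")
    labels = sorted(set().union(*(t.leaf_labels() for t in gene_trees)))
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    total = np.zeros((n, n))
    count = np.zeros((n, n))
    for tree in gene_trees:
        if tree.rooted:
            tree = tree.unrooted_copy()  # internode counts follow the unrooted topology
        for pair, d in _internode_counts(tree).items():
            a, b = pair
            i, j = index[a], index[b]
            total[i, j] += d
            total[j, i] += d
            count[i, j] += 1
            count[j, i] += 1
    off = ~np.eye(n, dtype=bool)
    if np.any(count[off] == 0):
        i, j = np.argwhere((count == 0) & off)[0]
        raise MatrixError(
            f"taxa {labels[i]!r} and {labels[j]!r} never co-occur in a gene tree"
        )
    values = np.zeros((n, n))
    values[off] = total[off] / count[off]
    return DistanceMatrix(labels, values)


# -- log-det ---------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    return np.array([_NUC.get(c, -1) for c in seq], dtype=np.int8)


def logdet_matrix(alignment: Alignment) -> DistanceMatrix:
    """Paralinear (log-det) distance matrix from an alignment.

    For each pair, let F be the 4x4 matrix of relative joint frequencies
    over sites where both sequences show a plain nucleotide, and let f, g
    be its row and column marginals.  The distance is

        d = -(1/4) * [ ln det F  -  (1/2) * ln( prod_a f_a * prod_a g_a ) ]

    which is additive (and equals expected substitutions per site under
    Jukes-Cantor).  Saturated pairs (det F <= 0 or a zero marginal) raise
    :class:`SaturationError` naming the pair rather than being capped.
    """
    labels = alignment.labels
    if len(labels) < 2:
        raise MatrixError("need at least two sequences")
    coded = {l: _encode(alignment.records[l]) for l in labels}
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = coded[labels[i]], coded[labels[j]]
            ok = (a >= 0) & (b >= 0)
            if not np.any(ok):
                raise MatrixError(
                    f"no pairwise-complete sites for {labels[i]!r}/{labels[j]!r}"
                )
            F = np.zeros((4, 4))
            np.add.at(F, (a[ok], b[ok]), 1.0)
            F /= F.sum()
            f = F.sum(axis=1)
            g = F.sum(axis=0)
            det = np.linalg.det(F)
            if det <= 0 or np.any(f == 0) or np.any(g == 0):
                raise SaturationError(
                    f"log-det distance undefined for pair "
                    f"({labels[i]!r}, {labels[j]!r}): saturated divergence matrix"
                )
            d = -0.25 * (np.log(det) - 0.5 * (np.sum(np.log(f)) + np.sum(np.log(g))))
            values[i, j] = values[j, i] = max(d, 0.0)
    return DistanceMatrix(labels, values)


# -- additive ---------------------------------------------------------------


def additive_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Pairwise path-length matrix of an edge-weighted binary tree."""
    for node in tree.iter_nodes():
        if node.parent is None:
            continue
        if node.length is None or node.length <= 0:
            raise TreeError("additive matrix requires strictly positive branch lengths")
    labels = sorted(tree.leaf_labels())
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    values = np.zeros((n, n))

    def walk(node: Node) -> list[tuple[str, float]]:
        if node.is_leaf:
            return [(node.label, 0.0)]
        groups = [
            [(leaf, d + (child.length or 0.0)) for leaf, d in walk(child)]
            for child in node.children
        ]
        for gi, gj in combinations(groups, 2):
            for a, da in gi:
                for b, db in gj:
                    i, j = index[a], index[b]
                    values[i, j] = values[j, i] = da + db
        return [item for g in groups for item in g]

    walk(tree.root)
    return DistanceMatrix(labels, values)


# -- PHYLIP I/O -------------------------------------------------------------


def read_matrix(path) -> DistanceMatrix:
    """Read a PHYLIP square distance matrix (n on the first line, then one
    row per taxon: label followed by n reals)."""
    with open(path) as handle:
        tokens_lines = [line.split() for line in handle if line.strip()]
    if not tokens_lines:
        raise MatrixError("empty matrix file")
    try:
        n = int(tokens_lines[0][0])
    except ValueError as exc:
        raise MatrixError("first line must give the taxon count") from exc
    rows = tokens_lines[1:]
    if len(rows) != n:
        raise MatrixError(f"expected {n} rows, found {len(rows)}")
    labels, values = [], np.zeros((n, n))
    for i, row in enumerate(rows):
        if len(row) != n + 1:
            raise MatrixError(f"row {i + 1}: expected label + {n} values")
        labels.append(row[0])
        values[i] = [float(v) for v in row[1:]]
    return DistanceMatrix(labels, values)


def write_matrix(matrix: DistanceMatrix, path) -> None:
    with open(path, "w") as handle:
        handle.write(f"{len(matrix)}\n")
        for label, row in zip(matrix.labels, matrix.values):
            vals = " ".join(f"{v:.9f}" for v in row)
            handle.write(f"{label} {vals}\n")
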