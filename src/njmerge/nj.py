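"""Classic Neighbor Joining: the Q criterion, sibling joins, and the matrix
update.  NJMerge shares these formulas verbatim and differs only in which
proposal it accepts, so the join machinery lives here as a reusable
:class:`JoinState`.

Q follows the Studier-Keppler O(n^3) formulation:

    Q[i, j] = (r - 2) * D[i, j] - sum_k D[i, k] - sum_k D[j, k]

with r the number of active nodes.  Ties in Q are broken lexicographically
on the sorted label pair, which makes every routine deterministic and
label-permutation equivariant.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .distances import DistanceMatrix
from .errors import DegenerateInputError, TreeError
from .tree import Node, PhyloTree

__all__ = ["JoinState", "q_matrix", "nj_tree"]


def q_matrix(D: DistanceMatrix) -> np.ndarray:
    """The NJ selection criterion; diagonal entries are set to +inf."""
    r = len(D)
    if r < 3:
        raise DegenerateInputError("Q requires at least 3 active nodes")
    V = D.values
    sums = V.sum(axis=1)
    Q = (r - 2) * V - sums[:, None] - sums[None, :]
    np.fill_diagonal(Q, np.inf)
    return Q


class JoinState:
    """The evolving state of an NJ-style agglomeration.

    Tracks the active node labels, the current distance matrix over them,
    the rooted subtree owned by each active node (leaves are original
    taxa), and the ordered log of accepted joins.
    """

    def __init__(self, D: DistanceMatrix):
        self.labels: list[str] = list(D.labels)
        self.matrix: np.ndarray = D.values.copy()
        self.subtrees: dict[str, Node] = {l: Node(l) for l in self.labels}
        self.join_log: list[tuple[str, str, str]] = []
        self._counter = 0

    @property
    def r(self) -> int:
        return len(self.labels)

    def q(self) -> np.ndarray:
        # computed directly: intermediate NJ matrices may carry negative
        # entries on non-additive input, which the DistanceMatrix container
        # (for *input* dissimilarities) deliberately rejects
        r = self.r
        if r < 3:
            raise DegenerateInputError("Q requires at least 3 active nodes")
        V = self.matrix
        sums = V.sum(axis=1)
        Q = (r - 2) * V - sums[:, None] - sums[None, :]
        np.fill_diagonal(Q, np.inf)
        return Q

    def sorted_proposals(self) -> list[tuple[str, str]]:
        """All active pairs in ascending Q order, ties broken on the sorted
        label pair."""
        Q = self.q()
        iu, ju = np.triu_indices(self.r, k=1)
        order = sorted(
            range(len(iu)),
            key=lambda k: (
                Q[iu[k], ju[k]],
                tuple(sorted((self.labels[iu[k]], self.labels[ju[k]]))),
            ),
        )
        return [(self.labels[iu[k]], self.labels[ju[k]]) for k in order]

    def fresh_label(self) -> str:
        """An internal merged-node identifier never colliding with taxa."""
        while True:
            self._counter += 1
            cand = f"@z{self._counter}"
            if cand not in self.labels:
                return cand

    def join(self, x: str, y: str, z: Optional[str] = None) -> str:
        """Make x and y siblings under a new active node z and update D with
        D[z, k] = (D[x, k] + D[y, k] - D[x, y]) / 2."""
        if x not in self.labels or y not in self.labels:
            raise TreeError(f"inactive label in join: ({x!r}, {y!r})")
        if x == y:
            raise TreeError("cannot join a label with itself")
        z = z or self.fresh_label()
        i, j = self.labels.index(x), self.labels.index(y)
        V = self.matrix
        dxy = V[i, j]
        row = 0.5 * (V[i] + V[j] - dxy)
        keep = [k for k in range(self.r) if k not in (i, j)]
        new = np.zeros((len(keep) + 1, len(keep) + 1))
        new[:-1, :-1] = V[np.ix_(keep, keep)]
        new[-1, :-1] = row[keep]
        new[:-1, -1] = row[keep]
        parent = Node()
        parent.add_child(self.subtrees.pop(x))
        parent.add_child(self.subtrees.pop(y))
        self.subtrees[z] = parent
        self.labels = [self.labels[k] for k in keep] + [z]
        self.matrix = new
        self.join_log.append((x, y, z))
        return z

    def close(self) -> PhyloTree:
        """Connect the last 3 (or 2) active nodes and return the unrooted
        tree on the original leaf set."""
        if self.r not in (2, 3):
            raise DegenerateInputError(f"cannot close with {self.r} active nodes")
        hub = Node()
        for label in self.labels:
            hub.add_child(self.subtrees[label])
        return PhyloTree(hub, rooted=False)


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Neighbor Joining: repeatedly join the argmin-Q pair until 3 active
    nodes remain, then close the tree.  Returns an unrooted binary tree on
    the matrix's label set; all downstream contracts are topological."""
    if len(D) < 3:
        raise DegenerateInputError("NJ requires at least 3 taxa")
    state = JoinState(D)
    while state.r > 3:
        x, y = state.sorted_proposals()[0]
        state.join(x, y)
    return state.close()
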