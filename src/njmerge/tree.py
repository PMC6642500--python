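"""Tree data model, Newick I/O and tree surgery primitives.

Trees are stored as rooted node structures.  Unrooted trees use an
arbitrary internal anchoring (the stored "root" is a degree-3 internal
node for n >= 3); all topology comparisons in this package go through
bipartition sets, so the anchoring never leaks into semantics.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Optional

import dendropy

from .errors import (
    AlignmentError,
    DegenerateInputError,
    NewickParseError,
    TreeError,
)

__all__ = [
    "Node",
    "PhyloTree",
    "Alignment",
    "parse_newick",
    "write_newick",
    "restrict",
    "root_at_leaf",
    "read_alignment",
]


class Node:
    """A tree node: leaves carry a label, internal nodes carry children."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label!r} deg={len(self.children)}>"


class PhyloTree:
    """A phylogenetic tree with unique leaf labels and optional branch lengths.

    Parameters
    ----------
    root:
        Root node of the underlying node structure.
    rooted:
        If True the root is semantically meaningful (degree 2 for a binary
        rooted tree); if False the root is only an anchoring device.
    """

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        self._validate_labels()

    # -- basic accessors ---------------------------------------------------

    def _validate_labels(self) -> None:
        seen = set()
        for leaf in self.iter_leaves():
            if not leaf.label:
                raise TreeError("leaf with empty label")
            if leaf.label in seen:
                raise TreeError(f"duplicate leaf label: {leaf.label!r}")
            seen.add(leaf.label)

    def iter_nodes(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def iter_leaves(self) -> Iterator[Node]:
        for node in self.iter_nodes():
            if node.is_leaf:
                yield node

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(leaf.label for leaf in self.iter_leaves())

    def __len__(self) -> int:
        return sum(1 for _ in self.iter_leaves())

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root), rooted=self.rooted)

    def unrooted_copy(self) -> "PhyloTree":
        """Forget the root: return an unrooted copy with a degree-3 anchor."""
        clone = self.copy()
        root = clone.root
        if len(root.children) == 2:
            root = _unroot_anchor(root)
        return PhyloTree(root, rooted=False)

    def find_leaf(self, label: str) -> Node:
        for leaf in self.iter_leaves():
            if leaf.label == label:
                return leaf
        raise TreeError(f"leaf not in tree: {label!r}")

    def is_binary(self) -> bool:
        """True if every internal node has the degree a binary tree demands."""
        n = len(self)
        if n <= 2:
            return True
        for node in self.iter_nodes():
            if node.is_leaf:
                continue
            deg = len(node.children) + (0 if node.parent is None else 1)
            if node.parent is None:
                want = 2 if self.rooted else 3
                if n == 3 and not self.rooted:
                    want = 3
                if deg != want:
                    return False
            elif deg != 3:
                return False
        return True

    # -- topology ----------------------------------------------------------

    def clusters(self) -> set[frozenset[str]]:
        """Leaf sets below each non-root node (rooted clades)."""
        out: set[frozenset[str]] = set()

        def walk(node: Node) -> frozenset[str]:
            if node.is_leaf:
                below = frozenset([node.label])
            else:
                below = frozenset().union(*(walk(c) for c in node.children))
            if node.parent is not None:
                out.add(below)
            return below

        walk(self.root)
        return out

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Nontrivial splits induced by internal edges.

        Each split is a frozenset of the two complementary leaf-label sets,
        so the representation is independent of the anchoring.
        """
        all_leaves = self.leaf_labels()
        n = len(all_leaves)
        splits: set[frozenset[frozenset[str]]] = set()
        for below in self.clusters():
            if 2 <= len(below) <= n - 2:
                splits.add(frozenset([below, all_leaves - below]))
        return splits

    def is_isomorphic_unrooted(self, other: "PhyloTree") -> bool:
        return (
            self.leaf_labels() == other.leaf_labels()
            and self.bipartitions() == other.bipartitions()
        )

    def is_isomorphic_rooted(self, other: "PhyloTree") -> bool:
        return (
            self.leaf_labels() == other.leaf_labels()
            and self.clusters() == other.clusters()
        )

    def has_cherry(self, x: str, y: str) -> bool:
        """True iff leaves x and y are attached to a common node."""
        lx = self.find_leaf(x)
        ly = self.find_leaf(y)
        return lx.parent is not None and lx.parent is ly.parent

    def __repr__(self) -> str:  # pragma: no cover
        kind = "rooted" if self.rooted else "unrooted"
        return f"<PhyloTree {kind} n={len(self)}>"


# -- Newick I/O ------------------------------------------------------------


def _from_dendropy(dnode) -> Node:
    node = Node(
        dnode.taxon.label if dnode.taxon is not None else None,
        dnode.edge.length,
    )
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    if node.is_leaf and node.label is None:
        raise NewickParseError("leaf without a label")
    return node


def _unroot_anchor(root: Node) -> Node:
    """Collapse a degree-2 anchoring so the stored root has degree 3."""
    while len(root.children) == 2 and any(not c.is_leaf for c in root.children):
        internal = next(c for c in root.children if not c.is_leaf)
        other = next(c for c in root.children if c is not internal)
        if other.length is not None or internal.length is not None:
            other.length = (other.length or 0.0) + (internal.length or 0.0)
        internal.children.append(other)
        other.parent = internal
        internal.parent = None
        internal.length = None
        root = internal
        break
    return root


def parse_newick(text: str, rooted: bool = False) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Branch lengths are optional; internal node labels are ignored; quoted
    labels are rejected.  ``rooted=False`` (the default) stores the tree
    with a degree-3 anchoring so the placement of the outermost parentheses
    carries no meaning.
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError(
            f"Newick string must end with ';' (got ...{stripped[-10:]!r}"
            f" at position {len(stripped)})"
        )
    if "'" in stripped or '"' in stripped:
        pos = min(i for i, c in enumerate(stripped) if c in "'\"")
        raise NewickParseError(f"quoted labels are unsupported (position {pos})")
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    root.length = None
    if not rooted and len(root.children) == 2:
        root = _unroot_anchor(root)
    return PhyloTree(root, rooted=rooted)


def _node_newick(node: Node, with_lengths: bool) -> str:
    if node.is_leaf:
        body = node.label
    else:
        inner = ",".join(_node_newick(c, with_lengths) for c in node.children)
        body = f"({inner})"
    if with_lengths and node.length is not None:
        return f"{body}:{node.length!r}"  # shortest exact float round trip
    return body


def write_newick(tree: PhyloTree, with_lengths: bool = True) -> str:
    """Serialize a tree to Newick; inverse of :func:`parse_newick` up to
    rotation and anchoring."""
    return _node_newick(tree.root, with_lengths) + ";"


# -- surgery ---------------------------------------------------------------


def restrict(tree: PhyloTree, subset: Iterable[str]) -> PhyloTree:
    """Restrict ``tree`` to ``subset``, suppressing degree-2 nodes.

    Every bipartition of the result is the restriction of a bipartition of
    the input.  Branch lengths along suppressed paths are summed, so path
    lengths between retained leaves are preserved.
    """
    wanted = frozenset(subset)
    have = tree.leaf_labels()
    unknown = wanted - have
    if unknown:
        raise TreeError(f"labels not in tree: {sorted(unknown)}")
    if not wanted:
        raise TreeError("cannot restrict to an empty leaf set")

    def keep(node: Node) -> Optional[Node]:
        if node.is_leaf:
            if node.label in wanted:
                return Node(node.label, node.length)
            return None
        kept = [k for k in (keep(c) for c in node.children) if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            if child.length is not None or node.length is not None:
                child.length = (child.length or 0.0) + (node.length or 0.0)
            return child
        new = Node(node.label, node.length)
        for k in kept:
            new.add_child(k)
        return new

    root = keep(tree.root)
    assert root is not None
    root.parent = None
    if tree.rooted:
        root.length = None
        return PhyloTree(root, rooted=True)
    # re-anchor so the stored root is internal of degree >= 3 when possible
    if root.is_leaf and len(wanted) == 1:
        root.length = None
        return PhyloTree(root, rooted=False)
    if root.is_leaf:
        # single leaf hanging below: pull structure up
        raise AssertionError("unreachable for multi-leaf restriction")
    if len(root.children) == 2:
        root = _unroot_anchor(root)
    root.length = None
    return PhyloTree(root, rooted=False)


def root_at_leaf(tree: PhyloTree, leaf: str) -> PhyloTree:
    """Root an unrooted tree at the attachment node of ``leaf``, removing
    the leaf itself.

    The result is a rooted tree on ``leaves(tree) - {leaf}``; for a binary
    input on n >= 4 leaves the root has degree 2.  This is the rooting
    device used to test pairwise constraint-tree compatibility: after a
    join both trees contain the merged leaf z, and rooting them at z turns
    unrooted compatibility into rooted compatibility.
    """
    if len(tree) < 3:
        raise DegenerateInputError("rooting requires a tree on >= 3 leaves")
    work = tree.copy()
    node = work.find_leaf(leaf)
    attach = node.parent
    if attach is None:
        raise TreeError(f"leaf {leaf!r} is the tree anchor; tree too small")
    # reorient so `attach` becomes the root
    path = []
    cur = attach
    while cur is not None:
        path.append(cur)
        cur = cur.parent
    orig_lengths = [nd.length for nd in path]
    for i in range(len(path) - 1):
        child, parent = path[i], path[i + 1]
        parent.children.remove(child)
        child.children.append(parent)
        parent.parent = child
        parent.length = orig_lengths[i]
    attach.parent = None
    attach.length = None
    attach.children.remove(node)
    root = attach
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        root.length = None
    return PhyloTree(root, rooted=True)


# -- alignments ------------------------------------------------------------


class Alignment:
    """A multiple sequence alignment: label -> equal-length string."""

    def __init__(self, records: dict[str, str]):
        if not records:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in records.values()}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged sequence lengths: {sorted(lengths)}")
        self.records = {k: v.upper() for k, v in records.items()}
        self.length = lengths.pop()

    @property
    def labels(self) -> list[str]:
        return list(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_alignment(path) -> Alignment:
    """Read a FASTA alignment; sequences are case-folded to uppercase."""
    from Bio import SeqIO

    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise AlignmentError(f"duplicate sequence label: {rec.id!r}")
        records[rec.id] = str(rec.seq)
    return Alignment(records)


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as handle:
        for label, seq in aln.records.items():
            handle.write(f">{label}\n{seq}\n")
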