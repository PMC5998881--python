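"""Taxon indexing, newick I/O, and the bipartition/clade/tripartition calculus.

Clades are represented as integer bitmasks over a :class:`TaxonIndex`; a set
bit at position *i* means the taxon with index *i* is a member.  All topology
comparisons in this package are purely set-theoretic on these masks, so trees
carry only labels and structure — branch lengths and input support annotations
are read and discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = [
    "TreeError",
    "NewickParseError",
    "TaxonIndex",
    "Node",
    "Tree",
    "Bipartition",
    "Tripartition",
    "parse_newick",
    "read_newick_file",
    "write_newick",
    "bipartitions_of",
    "tripartitions_of",
    "restrict",
    "unroot",
    "root_at_edge",
    "all_rootings",
    "canonical_form",
]


class TreeError(ValueError):
    """Validation failure on a tree, label set, or bipartition."""


class NewickParseError(TreeError):
    """Malformed newick input."""


def popcount(mask: int) -> int:
    return mask.bit_count()


def lowest_bit(mask: int) -> int:
    """Index of the lowest set bit."""
    return (mask & -mask).bit_length() - 1


def iter_bits(mask: int) -> Iterator[int]:
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


class TaxonIndex:
    """Immutable bijection between taxon labels and indices ``0..n-1``.

    The index order is fixed for the lifetime of a run; by convention it is
    first-appearance order across the input files unless an explicit label
    list is supplied.
    """

    __slots__ = ("labels", "_index")

    def __init__(self, labels: Iterable[str]):
        labels = tuple(labels)
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate taxon labels in taxon index")
        if any(not lab for lab in labels):
            raise TreeError("empty taxon label")
        self.labels = labels
        self._index = {lab: i for i, lab in enumerate(labels)}

    @property
    def n(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise TreeError(f"label {label!r} not in taxon index") from None

    def mask_of(self, labels: Iterable[str]) -> int:
        mask = 0
        for lab in labels:
            mask |= 1 << self.index(lab)
        return mask

    def labels_of(self, mask: int) -> list[str]:
        return [self.labels[i] for i in iter_bits(mask)]

    @property
    def full_mask(self) -> int:
        return (1 << self.n) - 1

    @classmethod
    def from_trees(cls, trees: Iterable["Tree"]) -> "TaxonIndex":
        """Taxon index in first-appearance order across the given trees."""
        seen: dict[str, None] = {}
        for t in trees:
            for lab in t.leaf_labels():
                seen.setdefault(lab)
        return cls(seen)


class Node:
    """A tree node: a leaf (``label`` set) or an internal node with children."""

    __slots__ = ("label", "children")

    def __init__(self, label: Optional[str] = None,
                 children: Optional[list["Node"]] = None):
        self.label = label
        self.children = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        if self.is_leaf:
            return Node(label=self.label)
        return Node(children=[c.copy() for c in self.children])


class Tree:
    """A phylogenetic tree with string leaf labels.

    ``rooted`` distinguishes a genuinely rooted tree (root of degree 2) from
    an unrooted topology stored with an arbitrary internal node as the root
    (degree >= 3 there).  Polytomies are permitted.
    """

    __slots__ = ("root", "rooted")

    def __init__(self, root: Node, rooted: bool):
        self.root = root
        self.rooted = rooted

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), self.rooted)

    def leaf_labels(self) -> list[str]:
        out: list[str] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node.label)
            else:
                stack.extend(reversed(node.children))
        return out

    def leaf_mask(self, taxa: TaxonIndex) -> int:
        return taxa.mask_of(self.leaf_labels())

    def n_leaves(self) -> int:
        return len(self.leaf_labels())

    def is_binary(self) -> bool:
        """True if every internal node is bifurcating (the root of an
        unrooted representation may be trifurcating)."""
        stack = [(self.root, True)]
        while stack:
            node, is_root = stack.pop()
            if node.is_leaf:
                continue
            k = len(node.children)
            limit = 2 if (self.rooted or not is_root) else 3
            if k != limit:
                return False
            stack.extend((c, False) for c in node.children)
        return True


@dataclass(frozen=True, order=True)
class Bipartition:
    """An unordered split {side | universe \\ side}, canonicalized so that
    ``side`` is the half NOT containing the lowest-indexed taxon present in
    ``universe``.  For complete trees the universe is the full taxon set; for
    incomplete trees it is the tree's own leaf set."""

    side: int
    universe: int

    def __post_init__(self):
        uni = self.universe
        side = self.side
        if side == 0 or side == uni or side & ~uni:
            raise TreeError("bipartition side must be a proper non-empty "
                            "subset of its universe")
        if side & (uni & -uni):
            object.__setattr__(self, "side", uni & ~side)

    @property
    def other(self) -> int:
        return self.universe & ~self.side

    def is_trivial(self) -> bool:
        return popcount(self.side) < 2 or popcount(self.other) < 2

    def pretty(self, taxa: TaxonIndex) -> str:
        a = ",".join(taxa.labels_of(self.other))
        b = ",".join(taxa.labels_of(self.side))
        return f"{a}|{b}"


@dataclass(frozen=True, order=True)
class Tripartition:
    """The (A, B, C) partition induced by an internal node of a rooted binary
    tree: A and B are the child clades, C the rest of the taxon set (empty at
    the root).  (A,B,C) and (B,A,C) are the same tripartition; canonical form
    stores the numerically smaller clade first."""

    a: int
    b: int
    c: int

    def __post_init__(self):
        if self.a == 0 or self.b == 0:
            raise TreeError("tripartition requires non-empty A and B")
        if (self.a & self.b) or (self.a & self.c) or (self.b & self.c):
            raise TreeError("tripartition parts must be pairwise disjoint")
        if self.a > self.b:
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)


# ---------------------------------------------------------------------------
# Newick I/O (via dendropy; branch lengths and internal labels discarded)
# ---------------------------------------------------------------------------

def _convert_dendropy(dnode) -> Node:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        if not label:
            raise NewickParseError("leaf with empty label")
        return Node(label=str(label))
    children = [_convert_dendropy(c) for c in dnode.child_nodes()]
    if len(children) == 1:      # suppress unifurcation
        return children[0]
    return Node(children=children)


def parse_newick(text: str, taxa: Optional[TaxonIndex] = None) -> Tree:
    """Parse a single newick string into a normalized :class:`Tree`.

    Branch lengths and internal-node labels are accepted and ignored.
    Raises :class:`NewickParseError` on malformed input (the message names
    the position dendropy reports) and :class:`TreeError` for duplicate leaf
    labels or labels absent from a supplied taxon index.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed newick: {exc}") from exc
    root = _convert_dendropy(dtree.seed_node)
    if root.is_leaf:
        raise NewickParseError("tree has fewer than 2 leaves")
    tree = Tree(root, rooted=(len(root.children) == 2))
    labels = tree.leaf_labels()
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate leaf label(s): {', '.join(dup)}")
    if taxa is not None:
        for lab in labels:
            if lab not in taxa:
                raise TreeError(f"leaf label {lab!r} not in taxon index")
    return tree


def read_newick_file(path, taxa: Optional[TaxonIndex] = None) -> list[Tree]:
    """Read a multi-newick file, one tree per line (blank lines skipped)."""
    trees = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                trees.append(parse_newick(line, taxa=taxa))
            except TreeError as exc:
                raise type(exc)(f"{path}:{lineno}: {exc}") from exc
    return trees


def _node_mask(node: Node, taxa: TaxonIndex) -> int:
    if node.is_leaf:
        return 1 << taxa.index(node.label)
    mask = 0
    for c in node.children:
        mask |= _node_mask(c, taxa)
    return mask


def write_newick(tree: Tree, taxa: Optional[TaxonIndex] = None,
                 support: Optional[dict] = None) -> str:
    """Deterministic newick serialization.

    Children are ordered by the smallest taxon index (or lexicographically
    smallest label when no taxon index is given) in their subtree.  ``support``
    maps :class:`Bipartition` (over the tree's own leaf universe) to a
    numeric value written as an internal-node label with 6 decimal places.
    """
    if support is not None and taxa is None:
        raise TreeError("support annotation requires a taxon index")
    universe = tree.leaf_mask(taxa) if taxa is not None else 0
    if support:
        own = bipartitions_of(tree, taxa)
        for bip in support:
            if bip not in own:
                raise TreeError(
                    f"support key {bip.pretty(taxa)} is not a bipartition "
                    f"of the tree")

    def fmt(node: Node, is_root: bool) -> str:
        if node.is_leaf:
            return node.label
        if taxa is not None:
            kids = sorted(node.children,
                          key=lambda c: lowest_bit(_node_mask(c, taxa)))
        else:
            kids = sorted(node.children, key=_min_label)
        body = "(" + ",".join(fmt(c, False) for c in kids) + ")"
        if support and not is_root:
            mask = _node_mask(node, taxa)
            if 2 <= popcount(mask) <= popcount(universe) - 2:
                bip = Bipartition(mask, universe)
                if bip in support:
                    return body + f"{float(support[bip]):.6f}"
        return body

    return fmt(tree.root, True) + ";"


def _min_label(node: Node) -> str:
    if node.is_leaf:
        return node.label
    return min(_min_label(c) for c in node.children)


# ---------------------------------------------------------------------------
# Bipartitions / tripartitions / restriction
# ---------------------------------------------------------------------------

def bipartitions_of(tree: Tree, taxa: TaxonIndex) -> set[Bipartition]:
    """Non-trivial bipartitions of the tree over its OWN leaf set.

    One bipartition per internal edge; for a rooted tree the two edges at the
    root induce the same split and contribute a single bipartition.
    """
    universe = tree.leaf_mask(taxa)
    out: set[Bipartition] = set()

    def walk(node: Node) -> int:
        if node.is_leaf:
            return 1 << taxa.index(node.label)
        mask = 0
        for c in node.children:
            mask |= walk(c)
        if node is not tree.root:
            if 2 <= popcount(mask) <= popcount(universe) - 2:
                out.add(Bipartition(mask, universe))
        return mask

    walk(tree.root)
    return out


def tripartitions_of(tree: Tree, taxa: TaxonIndex) -> list[Tripartition]:
    """Tripartitions of a complete rooted binary tree, one per internal node
    (n-1 of them); C is empty exactly at the root."""
    if not tree.rooted:
        raise TreeError("tripartitions require a rooted tree")
    full = taxa.full_mask
    if tree.leaf_mask(taxa) != full:
        raise TreeError("tripartitions require a complete tree")
    out: list[Tripartition] = []

    def walk(node: Node) -> int:
        if node.is_leaf:
            return 1 << taxa.index(node.label)
        if len(node.children) != 2:
            raise TreeError("tripartitions require a binary tree")
        a = walk(node.children[0])
        b = walk(node.children[1])
        out.append(Tripartition(a, b, full & ~(a | b)))
        return a | b

    walk(tree.root)
    return out


def restrict(tree: Tree, leaves, taxa: TaxonIndex) -> Tree:
    """Induced subtree on ``leaves`` (a bitmask or iterable of labels),
    with unifurcations suppressed."""
    if not isinstance(leaves, int):
        leaves = taxa.mask_of(leaves)
    if tree.leaf_mask(taxa) & leaves == 0:
        raise TreeError("restriction to an empty leaf intersection")

    def prune(node: Node) -> Optional[Node]:
        if node.is_leaf:
            if (1 << taxa.index(node.label)) & leaves:
                return Node(label=node.label)
            return None
        kids = [k for k in (prune(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return Node(children=kids)

    root = prune(tree.root)
    return Tree(root, rooted=(len(root.children) == 2) and tree.rooted)


# ---------------------------------------------------------------------------
# Rooting / unrooting / canonical form
# ---------------------------------------------------------------------------

def unroot(tree: Tree) -> Tree:
    """Suppress a degree-2 root, returning an unrooted representation whose
    root is an internal node of degree >= 3."""
    root = tree.root.copy()
    while len(root.children) == 2:
        left, right = root.children
        if not left.is_leaf:
            root = Node(children=left.children + [right])
        elif not right.is_leaf:
            root = Node(children=right.children + [left])
        else:
            break  # 2-leaf tree; nothing to suppress
    return Tree(root, rooted=False)


def _adjacency(tree: Tree, taxa: TaxonIndex):
    """Undirected adjacency of the unrooted topology.

    Returns (adj, labels) where node ids are ints, ``adj`` maps id -> sorted
    neighbor ids and ``labels`` maps leaf ids to labels.  Edge iteration over
    this structure is deterministic.
    """
    base = unroot(tree)
    adj: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    counter = [0]

    def new_id() -> int:
        counter[0] += 1
        return counter[0] - 1

    def walk(node: Node) -> int:
        nid = new_id()
        adj[nid] = []
        if node.is_leaf:
            labels[nid] = node.label
        for c in node.children:
            cid = walk(c)
            adj[nid].append(cid)
            adj[cid].append(nid)
        return nid

    walk(base.root)
    return adj, labels


def _subtree_from(adj, labels, node: int, parent: int) -> Node:
    if node in labels:
        return Node(label=labels[node])
    kids = [
        _subtree_from(adj, labels, nb, node)
        for nb in adj[node] if nb != parent
    ]
    return Node(children=kids)


def _edge_masks(adj, labels, taxa: TaxonIndex) -> dict[tuple[int, int], int]:
    """Mask of the leaf set on the ``v`` side of each directed edge (u, v)."""
    masks: dict[tuple[int, int], int] = {}

    def down(u: int, v: int) -> int:
        if (u, v) in masks:
            return masks[(u, v)]
        if v in labels:
            m = 1 << taxa.index(labels[v])
        else:
            m = 0
            for nb in adj[v]:
                if nb != u:
                    m |= down(v, nb)
        masks[(u, v)] = m
        return m

    for u in adj:
        for v in adj[u]:
            down(u, v)
    return masks


def all_rootings(tree: Tree, taxa: TaxonIndex) -> Iterator[Tree]:
    """All rootings of the unrooted topology of ``tree``, one per edge
    (pendant edges included): 2n-3 for a binary tree on n leaves."""
    adj, labels = _adjacency(tree, taxa)
    seen: set[frozenset] = set()
    for u in sorted(adj):
        for v in adj[u]:
            key = frozenset((u, v))
            if key in seen:
                continue
            seen.add(key)
            yield Tree(Node(children=[_subtree_from(adj, labels, u, v),
                                      _subtree_from(adj, labels, v, u)]),
                       rooted=True)


def root_at_edge(tree: Tree, bipartition: Bipartition,
                 taxa: TaxonIndex) -> Tree:
    """The unique rooting of ``tree`` whose root children have leaf sets
    equal to the two sides of ``bipartition`` (trivial splits allowed, to
    permit rooting on pendant edges)."""
    adj, labels = _adjacency(tree, taxa)
    masks = _edge_masks(adj, labels, taxa)
    want = {bipartition.side, bipartition.other}
    for (u, v), m in masks.items():
        if u < v and m in want and masks[(v, u)] in want:
            return Tree(Node(children=[_subtree_from(adj, labels, u, v),
                                       _subtree_from(adj, labels, v, u)]),
                        rooted=True)
    raise TreeError("bipartition is not an edge of the tree")


def canonical_form(tree: Tree, taxa: TaxonIndex) -> str:
    """A string equal across two complete trees iff their unrooted topologies
    are equal: the deterministic newick of the rooting at the pendant edge of
    the lowest-indexed leaf present."""
    mask = tree.leaf_mask(taxa)
    pivot = 1 << lowest_bit(mask)
    rooted = root_at_edge(tree, Bipartition(pivot, mask), taxa)
    return write_newick(rooted, taxa)
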