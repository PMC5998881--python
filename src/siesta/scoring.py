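"""The two optimization criteria as tripartition-weight functions.

Both criteria are maximized and integer-valued:

* the Robinson–Foulds supertree criterion, maximizing the total number of
  source-tree bipartitions shared with the supertree restricted to each
  source tree's leaf set (equivalently minimizing total RF distance), and
* the quartet criterion, maximizing the number of gene-tree quartet
  topologies that agree with the species tree.

Each criterion exposes two independent computation paths: a direct
whole-tree scorer F(T) computed from first principles (restriction and
4-subset enumeration), and a per-tripartition weight w such that for every
complete binary tree T whose bipartitions are allowed, and for every rooting
of T, the sum of w over the rooting's tripartitions equals F(T) exactly.
The direct path is the test oracle for the weight path.

Weight decomposition
--------------------
Write L for a source tree's leaf set and, at a tripartition (A, B, C), let
a = A∩L, b = B∩L, c = C∩L.  A non-trivial source bipartition P|Q is shared
with T restricted to L exactly when P (or Q) is a clade of the restricted
rooted tree; the minimal clade of the rooting whose intersection with L is P
is the unique node where both child clades meet L.  Counting each block at
that anchor gives

    N1(A,B,C) = [a != 0 and b != 0 and (a ∪ b) is a block of the source]

summed over both blocks of every source bipartition.  When the restricted
root joins the two blocks of a single bipartition (both P and Q are clades),
the bipartition is anchored twice; that happens at the unique node with
c = 0 and a, b both non-empty, where a|b is itself the source bipartition:

    N2(A,B,C) = [c == 0 and a != 0 and b != 0 and a is a block]

and w = N1 - N2 per source tree.  The quartet criterion is the same
decomposition applied to every 4-leaf restriction of every gene tree, which
reduces to closed-form pattern counts over the gene's resolved quartets.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional

from .trees import (
    TaxonIndex,
    Tree,
    TreeError,
    Tripartition,
    bipartitions_of,
    popcount,
    restrict,
)

__all__ = [
    "SourceTreeSet",
    "TripartitionScorer",
    "RFSupertreeScorer",
    "QuartetScorer",
    "make_scorer",
    "quartet_tree_score",
    "rfs_tree_score",
    "rfs_total_rf",
]


class SourceTreeSet:
    """The input source (or gene) trees; leaf sets may be proper subsets of
    S and polytomies are allowed, but each tree needs >= 4 leaves."""

    def __init__(self, trees: list[Tree], taxa: TaxonIndex):
        for i, t in enumerate(trees):
            if t.n_leaves() < 4:
                raise TreeError(f"source tree {i + 1} has fewer than 4 leaves")
        self.trees = list(trees)
        self.taxa = taxa
        self._leaf_masks: Optional[list[int]] = None
        self._block_sets: Optional[list[frozenset[int]]] = None
        self._quartets: Optional[list[list[tuple[int, int, int]]]] = None

    @property
    def k(self) -> int:
        return len(self.trees)

    @property
    def leaf_masks(self) -> list[int]:
        if self._leaf_masks is None:
            self._leaf_masks = [t.leaf_mask(self.taxa) for t in self.trees]
        return self._leaf_masks

    @property
    def block_sets(self) -> list[frozenset[int]]:
        """Per tree: every block (side mask) of every non-trivial bipartition.
        Within one tree, a mask determines its bipartition uniquely."""
        if self._block_sets is None:
            out = []
            for t, lm in zip(self.trees, self.leaf_masks):
                blocks: set[int] = set()
                for bip in bipartitions_of(t, self.taxa):
                    blocks.add(bip.side)
                    blocks.add(bip.other)
                out.append(frozenset(blocks))
            self._block_sets = out
        return self._block_sets

    @property
    def resolved_quartets(self) -> list[list[tuple[int, int, int]]]:
        """Per tree: (quartet_mask, block1, block2) for every 4-subset of its
        leaves whose induced topology is resolved; block1|block2 is that
        topology (each block a 2-bit mask).  Unresolved quartets (through a
        polytomy) are omitted."""
        if self._quartets is None:
            out = []
            for t in self.trees:
                out.append(_resolved_quartets(t, self.taxa))
            self._quartets = out
        return self._quartets


def _quartet_topologies(tree: Tree, taxa: TaxonIndex) -> dict[int, int]:
    """Map 4-subset mask -> the topology block containing the subset's
    lowest-indexed member (resolved quartets only)."""
    top: dict[int, int] = {}
    for bip in bipartitions_of(tree, taxa):
        p_bits = [1 << i for i in _bits(bip.side)]
        q_bits = [1 << i for i in _bits(bip.other)]
        for x, y in combinations(p_bits, 2):
            pb = x | y
            for z, w in combinations(q_bits, 2):
                qb = z | w
                qmask = pb | qb
                low = qmask & -qmask
                top[qmask] = pb if (pb & low) else qb
    return top


def _bits(mask: int):
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def _resolved_quartets(tree: Tree, taxa: TaxonIndex):
    top = _quartet_topologies(tree, taxa)
    out = []
    for qmask, b1 in sorted(top.items()):
        out.append((qmask, b1, qmask & ~b1))
    return out


# ---------------------------------------------------------------------------
# Direct (oracle-path) whole-tree scorers
# ---------------------------------------------------------------------------

def _check_complete_binary(tree: Tree, taxa: TaxonIndex) -> None:
    if tree.leaf_mask(taxa) != taxa.full_mask:
        raise TreeError("tree must be complete on the full taxon set")
    if not tree.is_binary():
        raise TreeError("tree must be binary")


def quartet_tree_score(tree: Tree, genes: SourceTreeSet) -> int:
    """Number of gene-tree quartets whose topology agrees with ``tree``,
    summed over genes, by direct 4-subset comparison."""
    taxa = genes.taxa
    _check_complete_binary(tree, taxa)
    ttop = _quartet_topologies(tree, taxa)
    score = 0
    for quartets in genes.resolved_quartets:
        for qmask, b1, b2 in quartets:
            tb = ttop.get(qmask)
            if tb is not None and (tb == b1 or tb == b2):
                score += 1
    return score


def rfs_tree_score(tree: Tree, sources: SourceTreeSet) -> int:
    """Total number of source-tree bipartitions shared with ``tree``
    restricted to each source tree's leaf set, by direct restriction."""
    taxa = sources.taxa
    _check_complete_binary(tree, taxa)
    score = 0
    for src, lm in zip(sources.trees, sources.leaf_masks):
        rest = restrict(tree, lm, taxa)
        score += len(bipartitions_of(rest, taxa)
                     & bipartitions_of(src, taxa))
    return score


def rfs_total_rf(tree: Tree, sources: SourceTreeSet) -> int:
    """Total Robinson–Foulds distance from ``tree`` to the source trees over
    their own leaf sets (the quantity the shared-bipartition score
    maximization minimizes)."""
    taxa = sources.taxa
    _check_complete_binary(tree, taxa)
    total = 0
    for src, lm in zip(sources.trees, sources.leaf_masks):
        rb = bipartitions_of(restrict(tree, lm, taxa), taxa)
        sb = bipartitions_of(src, taxa)
        total += len(rb) + len(sb) - 2 * len(rb & sb)
    return total


# ---------------------------------------------------------------------------
# Tripartition scorers (the DP path)
# ---------------------------------------------------------------------------

class TripartitionScorer:
    """Base class: integer tripartition weights with a memo cache, plus the
    matching direct tree scorer used for cross-checking."""

    name: str = ""
    direction: str = "max"

    def __init__(self, sources: SourceTreeSet):
        self.sources = sources
        self._cache: dict[Tripartition, int] = {}
        self.calls = 0  # raw weight evaluations (cache misses)

    def weight(self, tri: Tripartition) -> int:
        cached = self._cache.get(tri)
        if cached is not None:
            return cached
        self.calls += 1
        val = self._weight(tri)
        self._cache[tri] = val
        return val

    def weight_abc(self, a: int, b: int, c: int) -> int:
        return self.weight(Tripartition(a, b, c))

    def _weight(self, tri: Tripartition) -> int:
        raise NotImplementedError

    def tree_score(self, tree: Tree) -> int:
        """Direct first-principles score F(T); independent of the weights."""
        raise NotImplementedError

    def score_bounds(self, n: int) -> tuple[int, int]:
        raise NotImplementedError


class RFSupertreeScorer(TripartitionScorer):
    """Robinson–Foulds supertree criterion: maximize shared bipartitions."""

    name = "rfs"

    def _weight(self, tri: Tripartition) -> int:
        w = 0
        blocks = self.sources.block_sets
        for lm, blk in zip(self.sources.leaf_masks, blocks):
            a = tri.a & lm
            b = tri.b & lm
            if not a or not b:
                continue
            if (a | b) in blk:
                w += 1
            if tri.c & lm == 0 and a in blk:
                w -= 1
        return w

    def tree_score(self, tree: Tree) -> int:
        return rfs_tree_score(tree, self.sources)

    def score_bounds(self, n: int) -> tuple[int, int]:
        return 0, (n - 3) * self.sources.k


class QuartetScorer(TripartitionScorer):
    """Quartet-agreement criterion: maximize gene quartets consistent with
    the species tree."""

    name = "quartet"

    def _weight(self, tri: Tripartition) -> int:
        w = 0
        A, B, C = tri.a, tri.b, tri.c
        for quartets in self.sources.resolved_quartets:
            for qmask, b1, b2 in quartets:
                # anchor on a straddling block with the other block inside C
                if b2 & ~C == 0 and popcount(b1 & A) == 1 \
                        and popcount(b1 & B) == 1:
                    w += 1
                if b1 & ~C == 0 and popcount(b2 & A) == 1 \
                        and popcount(b2 & B) == 1:
                    w += 1
                # root-join correction: quartet fully inside A ∪ B, split
                # block-per-side
                if qmask & C == 0:
                    if (b1 & ~A == 0 and b2 & ~B == 0) or \
                            (b1 & ~B == 0 and b2 & ~A == 0):
                        w -= 1
        return w

    def tree_score(self, tree: Tree) -> int:
        return quartet_tree_score(tree, self.sources)

    def score_bounds(self, n: int) -> tuple[int, int]:
        return 0, self.sources.k * (n * (n - 1) * (n - 2) * (n - 3)) // 24


_SCORERS = {"rfs": RFSupertreeScorer, "quartet": QuartetScorer}


def make_scorer(criterion: str, sources: SourceTreeSet) -> TripartitionScorer:
    try:
        cls = _SCORERS[criterion]
    except KeyError:
        raise ValueError(f"unknown criterion {criterion!r}; "
                         f"choose from {sorted(_SCORERS)}") from None
    return cls(sources)
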