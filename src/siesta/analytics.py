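"""Analytics over the solution-space DAG.

Everything here is exact: optimal-tree counts are arbitrary-precision
integers, bipartition frequencies and support values are rational numbers,
and ties in consensus construction are broken by a documented canonical
order.  Decimals appear only at serialization time.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterator, Optional

from .dp_core import SiestaDAG, _build_rooted
from .trees import (
    Bipartition,
    Node,
    TaxonIndex,
    Tree,
    TreeError,
    bipartitions_of,
    canonical_form,
    iter_bits,
    popcount,
    unroot,
)

__all__ = [
    "SupportMap",
    "ErrorReport",
    "count_rooted_optima",
    "count_unrooted_optima",
    "bipartition_frequencies",
    "enumerate_optimal_trees",
    "sample_optimal_tree",
    "consensus",
    "corrected_support",
    "mcc_tree",
    "tree_error_rates",
    "tree_from_bipartitions",
]


@dataclass
class SupportMap:
    """Exact rational frequency (over the unrooted optima) of every
    bipartition that appears in at least one optimal tree."""

    frequencies: dict[Bipartition, Fraction]
    n: int
    unrooted_count: int

    def __getitem__(self, bip: Bipartition) -> Fraction:
        return self.frequencies[bip]

    def get(self, bip: Bipartition, default=Fraction(0)) -> Fraction:
        return self.frequencies.get(bip, default)

    def items(self):
        return self.frequencies.items()


@dataclass
class ErrorReport:
    """Topological error of an estimated tree against a binary model tree.

    FN and FP are the missing / spurious bipartition counts, each normalized
    by n - 3 (the internal-edge count of a binary unrooted tree on n taxa).
    """

    fn: Fraction
    fp: Fraction
    average: Fraction
    f1: Fraction


def count_rooted_optima(dag: SiestaDAG) -> int:
    """Exact number of distinct optimal rooted binary trees in the DAG."""
    return dag.optsubtrees()[dag.root]


def count_unrooted_optima(dag: SiestaDAG) -> int:
    """Exact number of distinct optimal unrooted trees.

    Every rooting of an unrooted tree scores identically under the built-in
    criteria, so each unrooted optimum has exactly 2n - 3 rooted
    representatives; non-divisibility signals a scorer that violates rooting
    invariance and raises an internal-consistency error.
    """
    rooted = count_rooted_optima(dag)
    denom = 2 * dag.n - 3
    q, r = divmod(rooted, denom)
    if r:
        raise ValueError(
            f"rooted optimum count {rooted} is not divisible by 2n-3 = "
            f"{denom}; the scoring function is not rooting-invariant")
    return q


def bipartition_frequencies(dag: SiestaDAG) -> SupportMap:
    """For each non-trivial bipartition present in >= 1 optimal tree, the
    exact fraction of unrooted optima containing it.

    The number of unrooted optima containing c | S\\c equals the number of
    optimal rooted trees rooted on that edge, optsubtrees(c) *
    optsubtrees(S\\c); dividing by the unrooted optimum count gives the
    frequency.
    """
    counts = dag.optsubtrees()
    full = dag.root
    unrooted = count_unrooted_optima(dag)
    freqs: dict[Bipartition, Fraction] = {}
    for a, b in dag.splits[full]:
        if popcount(a) < 2 or popcount(b) < 2:
            continue  # trivial bipartition (pendant-edge rooting)
        num = counts[a] * counts[b]
        if num:
            freqs[Bipartition(a, full)] = Fraction(num, unrooted)
    return SupportMap(frequencies=freqs, n=dag.n, unrooted_count=unrooted)


def enumerate_optimal_trees(dag: SiestaDAG,
                            limit: Optional[int] = None) -> Iterator[Tree]:
    """Yield every distinct optimal UNROOTED tree exactly once, in a
    deterministic order, stopping after ``limit`` trees if given.

    Rooted optima are generated by DAG traversal and deduplicated through
    the canonical unrooted form (each unrooted optimum has 2n - 3 rooted
    representatives).
    """
    if limit is not None and limit <= 0:
        raise ValueError("limit must be positive")
    taxa = dag.taxa
    seen: set[str] = set()
    emitted = 0

    def subtrees(c: int) -> Iterator[Node]:
        if popcount(c) == 1:
            yield Node(label=taxa.labels[next(iter_bits(c))])
            return
        for a, b in dag.splits[c]:
            for left in subtrees(a):
                for right in subtrees(b):
                    yield Node(children=[left.copy(), right.copy()])

    for root in subtrees(dag.root):
        tree = unroot(Tree(root, rooted=True))
        key = canonical_form(tree, taxa)
        if key in seen:
            continue
        seen.add(key)
        yield tree
        emitted += 1
        if limit is not None and emitted >= limit:
            return


def sample_optimal_tree(dag: SiestaDAG, seed: int) -> Tree:
    """Draw one optimal tree uniformly at random.

    At each clade a split is chosen with probability proportional to the
    number of optimal subtree combinations it admits, which makes the draw
    uniform over rooted optima and therefore uniform over unrooted optima.
    """
    rng = random.Random(seed)
    counts = dag.optsubtrees()

    def choose(c: int, splits):
        total = counts[c]
        pick = rng.randrange(total)
        acc = 0
        for a, b in splits:
            acc += counts[a] * counts[b]
            if pick < acc:
                return a, b
        raise AssertionError("split weights do not sum to optsubtrees")

    return unroot(_build_rooted(dag, choose))


# ---------------------------------------------------------------------------
# Consensus construction
# ---------------------------------------------------------------------------

def _compatible(side: int, accepted: list[int]) -> bool:
    """Laminar compatibility of canonical sides (none contains taxon 0)."""
    for s in accepted:
        inter = s & side
        if inter and inter != s and inter != side:
            return False
    return True


def tree_from_bipartitions(sides: list[int], taxa: TaxonIndex) -> Tree:
    """Build the (possibly multifurcating) unrooted tree containing exactly
    the given pairwise-compatible bipartitions; ``sides`` are canonical side
    masks (not containing taxon 0)."""
    full = taxa.full_mask
    clades = sorted(set(sides) | {1 << i for i in range(taxa.n)},
                    key=lambda m: (popcount(m), m))
    nodes: dict[int, Node] = {}
    available: list[int] = []
    for c in clades:
        if popcount(c) == 1:
            nodes[c] = Node(label=taxa.labels[next(iter_bits(c))])
        else:
            kids, rest = [], []
            for m in available:
                (kids if m & c == m else rest).append(m)
            covered = 0
            for m in kids:
                covered |= m
            if covered != c:
                raise TreeError("incompatible bipartition set")
            nodes[c] = Node(children=[nodes[m] for m in kids])
            available = rest
        available.append(c)
    root_kids = [nodes[m] for m in available]
    return Tree(Node(children=root_kids), rooted=False)


def consensus(dag: SiestaDAG, kind: str = "strict",
              alpha: Optional[Fraction] = None) -> Tree:
    """Consensus of the optimal trees: ``strict`` keeps bipartitions with
    frequency 1, ``majority`` those with frequency > 1/2, ``greedy`` inserts
    all bipartitions in descending frequency, skipping incompatible ones,
    and ``alpha`` thresholds at a supplied α in [0, 1): for α >= 1/2 the
    result is { frequency > α }; for α < 1/2 the accepted set may not form a
    tree, so greedy insertion is applied to it.

    Equal frequencies in greedy insertion are ordered by canonical
    bipartition side — a documented arbitrary tie-break, since the greedy
    consensus is not unique in general.
    """
    support = bipartition_frequencies(dag)
    return _consensus_from_support(support, dag.taxa, kind, alpha)


def _consensus_from_support(support: SupportMap, taxa: TaxonIndex,
                            kind: str, alpha: Optional[Fraction]) -> Tree:
    items = sorted(support.items(),
                   key=lambda kv: (-kv[1], min(kv[0].side, kv[0].other)))
    if kind == "strict":
        chosen = [b.side for b, a in items if a == 1]
        greedy = False
    elif kind == "majority":
        chosen = [b.side for b, a in items if a > Fraction(1, 2)]
        greedy = False
    elif kind == "greedy":
        chosen = [b.side for b, a in items]
        greedy = True
    elif kind == "alpha":
        if alpha is None or not (0 <= alpha < 1):
            raise ValueError("alpha consensus requires alpha in [0, 1)")
        chosen = [b.side for b, a in items if a > alpha]
        greedy = alpha < Fraction(1, 2)
    else:
        raise ValueError(f"unknown consensus kind {kind!r}")
    if greedy:
        accepted: list[int] = []
        for side in chosen:
            if _compatible(side, accepted):
                accepted.append(side)
        chosen = accepted
    return tree_from_bipartitions(chosen, taxa)


# ---------------------------------------------------------------------------
# Corrected support and the MCC heuristic
# ---------------------------------------------------------------------------

def corrected_support(tree: Tree, dag: SiestaDAG,
                      base_support: Optional[dict] = None) -> dict:
    """Support for each non-trivial bipartition of ``tree``, corrected for
    the existence of multiple optima.

    Without ``base_support`` the corrected value is the bipartition's
    frequency A across the optimal trees (an optimum lacking the bipartition
    contributes zero, so a split absent from all optima gets 0).  With
    ``base_support`` (raw per-bipartition values, e.g. posterior supports
    carried on an annotated tree), the corrected value is raw * A: the raw
    support down-weighted by the fraction of optima containing the split.
    """
    if tree.leaf_mask(dag.taxa) != dag.taxa.full_mask:
        raise TreeError("tree must be complete on the full taxon set")
    freqs = bipartition_frequencies(dag)
    out: dict[Bipartition, Fraction] = {}
    for bip in bipartitions_of(tree, dag.taxa):
        a = freqs.get(bip, Fraction(0))
        if base_support is not None:
            raw = Fraction(base_support.get(bip, 1))
            out[bip] = raw * a
        else:
            out[bip] = a
    return out


def mcc_tree(dag: SiestaDAG,
             base_support: Optional[dict] = None) -> tuple[Tree, dict]:
    """Greedy maximum-clade-credibility heuristic: rank every bipartition
    occurring in any optimum by corrected support (frequency A, or raw * A
    when raw supports are supplied) and build a greedy consensus in that
    order.  Returns the tree and its per-bipartition corrected supports."""
    freqs = bipartition_frequencies(dag)
    ranked: list[tuple[Bipartition, Fraction]] = []
    for bip, a in freqs.items():
        if base_support is not None:
            val = Fraction(base_support.get(bip, 1)) * a
        else:
            val = a
        ranked.append((bip, val))
    ranked.sort(key=lambda kv: (-kv[1], min(kv[0].side, kv[0].other)))
    accepted: list[int] = []
    values: dict[Bipartition, Fraction] = {}
    for bip, val in ranked:
        if _compatible(bip.side, accepted):
            accepted.append(bip.side)
            values[bip] = val
    tree = tree_from_bipartitions(accepted, dag.taxa)
    return tree, values


# ---------------------------------------------------------------------------
# Error metrics
# ---------------------------------------------------------------------------

def tree_error_rates(estimated: Tree, model: Tree,
                     taxa: TaxonIndex) -> ErrorReport:
    """FN/FP rates, their average, and the F1 score of an estimated tree
    against a binary model tree on the same leaf set."""
    em = estimated.leaf_mask(taxa)
    mm = model.leaf_mask(taxa)
    if em != mm:
        raise TreeError("estimated and model trees have different leaf sets")
    if not model.is_binary():
        raise TreeError("model tree must be binary")
    n = popcount(mm)
    denom = n - 3
    ce = bipartitions_of(estimated, taxa)
    cm = bipartitions_of(model, taxa)
    shared = len(ce & cm)
    fn = Fraction(len(cm) - shared, denom)
    fp = Fraction(len(ce) - shared, denom)
    if shared == 0:
        f1 = Fraction(0)
    else:
        precision = Fraction(shared, len(ce))
        recall = Fraction(shared, len(cm))
        f1 = 2 * precision * recall / (precision + recall)
    return ErrorReport(fn=fn, fp=fp, average=(fn + fp) / 2, f1=f1)
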