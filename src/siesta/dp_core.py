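"""Constrained exact optimization with all-optima bookkeeping.

The dynamic program processes allowed clades from smallest to largest.  For
a clade c it maximizes f(a) + f(b) + w(a, b, S \\ c) over the allowed splits
{a, b} of c, with f = 0 on singletons.  Instead of remembering one best
split per clade, every split attaining the optimum is recorded, so the
result is a directed acyclic graph that implicitly represents the complete
set of optimal rooted binary trees drawing their clades from the allowed
set.  All comparisons are exact integer comparisons; tie detection is the
entire point of the bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .constraints import TripartitionTable
from .scoring import TripartitionScorer
from .trees import Node, TaxonIndex, Tree, iter_bits, popcount, unroot

__all__ = ["InfeasibleError", "SiestaDAG", "run_dp", "extract_one_tree"]


class InfeasibleError(ValueError):
    """No complete binary tree exists within the allowed-bipartition set."""


@dataclass
class SiestaDAG:
    """The solution-space DAG.

    For every feasible allowed clade c: ``f[c]`` is the optimal score of a
    rooted binary subtree on c, and ``splits[c]`` is the list of every
    unordered pair (a, b) attaining it (sorted; empty for singletons).
    ``optsubtrees`` (the per-clade count of optimal rooted subtrees,
    arbitrary-precision) is filled lazily on the first analytics call.
    """

    taxa: TaxonIndex
    f: dict[int, int]
    splits: dict[int, list[tuple[int, int]]]
    direction: str = "max"
    criterion: str = ""
    _optsubtrees: Optional[dict[int, int]] = field(default=None, repr=False)

    @property
    def root(self) -> int:
        return self.taxa.full_mask

    @property
    def n(self) -> int:
        return self.taxa.n

    @property
    def optimal_score(self) -> int:
        return self.f[self.root]

    def optsubtrees(self) -> dict[int, int]:
        if self._optsubtrees is None:
            counts: dict[int, int] = {}
            for c in sorted(self.f, key=lambda m: (popcount(m), m)):
                if popcount(c) == 1:
                    counts[c] = 1
                else:
                    counts[c] = sum(counts[a] * counts[b]
                                    for a, b in self.splits[c])
            self._optsubtrees = counts
        return self._optsubtrees


def run_dp(table: TripartitionTable, scorer: TripartitionScorer,
           direction: str = "max") -> SiestaDAG:
    """Run the constrained DP and record every optimal split of every clade.

    Raises :class:`InfeasibleError`, naming a witness clade, when the full
    taxon set cannot be assembled from allowed clades.
    """
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    better = (lambda x, y: x > y) if direction == "max" else (lambda x, y: x < y)
    cs = table.cs
    taxa = cs.taxa
    if taxa.n < 4:
        raise ValueError("optimization requires at least 4 taxa")
    full = taxa.full_mask

    f: dict[int, int] = {}
    splits: dict[int, list[tuple[int, int]]] = {}
    for i in range(taxa.n):
        f[1 << i] = 0
        splits[1 << i] = []

    order = sorted((c for c in cs.clades if popcount(c) >= 2),
                   key=lambda m: (popcount(m), m))
    for c in order:
        rest = full & ~c
        best: Optional[int] = None
        best_splits: list[tuple[int, int]] = []
        for a, b in table.by_clade.get(c, ()):
            if a not in f or b not in f:
                continue  # infeasible subclade
            val = f[a] + f[b] + scorer.weight_abc(a, b, rest)
            if best is None or better(val, best):
                best = val
                best_splits = [(a, b)]
            elif val == best:
                best_splits.append((a, b))
        if best is not None:
            f[c] = best
            splits[c] = best_splits
    if full not in f:
        # name the largest root-reachable clade with no feasible split
        witness = max((c for c in cs.clades if c not in f),
                      key=lambda m: (popcount(m), -m))
        labels = taxa.labels_of(witness)
        raise InfeasibleError(
            "no complete binary tree within the allowed bipartitions; "
            f"clade {{{', '.join(labels)}}} has no feasible split")
    return SiestaDAG(taxa=taxa, f=f, splits=splits, direction=direction,
                     criterion=scorer.name)


def _build_rooted(dag: SiestaDAG, choose) -> Tree:
    """Build one rooted optimal tree, selecting a split per clade with
    ``choose(clade, splits) -> (a, b)``."""
    taxa = dag.taxa

    def build(c: int) -> Node:
        if popcount(c) == 1:
            return Node(label=taxa.labels[next(iter_bits(c))])
        a, b = choose(c, dag.splits[c])
        return Node(children=[build(a), build(b)])

    return Tree(build(dag.root), rooted=True)


def extract_one_tree(dag: SiestaDAG) -> Tree:
    """Deterministic single optimal tree: at each clade take the canonically
    smallest optimal split; returned unrooted."""
    return unroot(_build_rooted(dag, lambda c, sp: sp[0]))
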