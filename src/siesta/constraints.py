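"""The constrained search space: allowed bipartitions, clades, and splits.

A solution tree must draw every bipartition from the allowed set X, built
from user-supplied complete constraint trees.  The allowed-clade set consists
of both halves of every bipartition in X, all singletons, and the full taxon
set S; the DP then considers, for every allowed clade c, each way of splitting
c into two disjoint allowed clades.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .trees import (
    Bipartition,
    TaxonIndex,
    Tree,
    TreeError,
    bipartitions_of,
    popcount,
)

__all__ = ["ConstraintSet", "TripartitionTable", "build_constraint_set",
           "enumerate_splits", "parse_extra_bipartitions"]


@dataclass
class ConstraintSet:
    """Allowed bipartitions X over S and the derived allowed clades."""

    taxa: TaxonIndex
    X: frozenset[Bipartition]
    clades: frozenset[int]  # bitmasks

    @property
    def n(self) -> int:
        return self.taxa.n


@dataclass
class TripartitionTable:
    """For each allowed clade c with |c| >= 2, every unordered pair {a, b}
    of allowed clades with a ⊎ b = c.  The implied tripartition at c is
    (a, b, S \\ c); its third part is empty exactly when c = S.  Clades with
    no splits are retained (they are infeasible as subtree roots)."""

    cs: ConstraintSet
    by_clade: dict[int, list[tuple[int, int]]]

    def n_splits(self) -> int:
        return sum(len(v) for v in self.by_clade.values())


def build_constraint_set(constraint_trees: list[Tree],
                         taxa: TaxonIndex) -> ConstraintSet:
    """Union the bipartitions of complete constraint trees into X and derive
    the allowed clades.

    Every constraint tree must be complete on S (the allowed-bipartition set
    is conventionally produced by other methods as complete trees).  If no
    constraint tree is binary, feasibility of the DP is not guaranteed and a
    warning is issued; infeasibility is then detected downstream.
    """
    if not constraint_trees:
        raise TreeError("at least one constraint tree is required")
    full = taxa.full_mask
    X: set[Bipartition] = set()
    any_binary = False
    for i, tree in enumerate(constraint_trees):
        if tree.leaf_mask(taxa) != full:
            missing = taxa.labels_of(full & ~tree.leaf_mask(taxa))
            raise TreeError(
                f"constraint tree {i + 1} is incomplete (missing "
                f"{', '.join(missing[:5])}{'...' if len(missing) > 5 else ''}); "
                f"supply complete trees on all {taxa.n} taxa")
        X.update(bipartitions_of(tree, taxa))
        if tree.is_binary() and tree.n_leaves() >= 4:
            any_binary = True
    if not any_binary:
        warnings.warn("no binary constraint tree supplied; the constrained "
                      "optimization may be infeasible", stacklevel=2)
    return ConstraintSet(taxa=taxa, X=frozenset(X),
                         clades=frozenset(_derive_clades(X, taxa)))


def _derive_clades(X, taxa: TaxonIndex) -> set[int]:
    """Allowed clades: both halves of every allowed bipartition, S, and the
    sides of every trivial bipartition (each singleton and its complement).

    The trivial sides are present in every tree, and including the
    singleton complements makes every rooting of every feasible tree —
    pendant edges included — representable in the DP, which is what makes
    the rooted optimum count exactly (2n-3) times the unrooted one.
    """
    full = taxa.full_mask
    clades: set[int] = {full}
    for i in range(taxa.n):
        clades.add(1 << i)
        clades.add(full & ~(1 << i))
    for bip in X:
        clades.add(bip.side)
        clades.add(bip.other)
    return clades


def add_bipartitions(cs: ConstraintSet,
                     extra: set[Bipartition]) -> ConstraintSet:
    """Augment X with extra bipartitions (both halves become allowed clades)."""
    X = set(cs.X) | set(extra)
    return ConstraintSet(taxa=cs.taxa, X=frozenset(X),
                         clades=frozenset(_derive_clades(X, cs.taxa)))


def parse_extra_bipartitions(path, taxa: TaxonIndex) -> set[Bipartition]:
    """Read an augmentation file: each line is either a newick tree (complete
    on S) or a comma-separated taxon list naming one side of a bipartition."""
    from .trees import parse_newick

    full = taxa.full_mask
    out: set[Bipartition] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                if line.endswith(";"):
                    tree = parse_newick(line, taxa=taxa)
                    if tree.leaf_mask(taxa) != full:
                        raise TreeError("tree is incomplete")
                    out.update(bipartitions_of(tree, taxa))
                else:
                    side = taxa.mask_of(lab.strip()
                                        for lab in line.split(","))
                    out.add(Bipartition(side, full))
            except TreeError as exc:
                raise TreeError(f"{path}:{lineno}: {exc}") from exc
    return out


def enumerate_splits(cs: ConstraintSet) -> TripartitionTable:
    """All allowed splits {a, b} (a ⊎ b = c, both allowed clades) for every
    allowed clade c with |c| >= 2.

    For each clade c, it suffices to scan the allowed clades a that are
    proper subsets of c and test whether the complement c \\ a is allowed;
    pairs are deduplicated by requiring a < b numerically and stored sorted.
    """
    clade_set = cs.clades
    by_size: dict[int, list[int]] = {}
    for c in clade_set:
        by_size.setdefault(popcount(c), []).append(c)
    for v in by_size.values():
        v.sort()

    by_clade: dict[int, list[tuple[int, int]]] = {}
    sizes = sorted(by_size)
    for size in sizes:
        if size < 2:
            continue
        for c in by_size[size]:
            splits: list[tuple[int, int]] = []
            for asize in range(1, size // 2 + 1):
                half = (2 * asize == size)
                for a in by_size.get(asize, ()):
                    if a & ~c:
                        continue
                    b = c & ~a
                    if b not in clade_set:
                        continue
                    if half and a > b:
                        continue  # even split seen from both sides
                    splits.append((min(a, b), max(a, b)))
            splits.sort()
            by_clade[c] = splits
    return TripartitionTable(cs=cs, by_clade=by_clade)
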