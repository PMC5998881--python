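"""Brute-force oracles and seeded synthetic fixtures.

The oracle path scores candidate trees with the criteria's direct
whole-tree scorers (never the tripartition weights), keeping it fully
independent of the dynamic program it checks.  The fixture generator builds
small instances — a model tree, source trees obtained by leaf subsampling
and NNI perturbation, and constraint trees that induce score ties — without
simulating sequence evolution or coalescent processes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterator, Optional

from .constraints import ConstraintSet
from .scoring import SourceTreeSet, TripartitionScorer
from .trees import (
    Node,
    TaxonIndex,
    Tree,
    bipartitions_of,
    restrict,
    unroot,
)

__all__ = [
    "FixtureSpec",
    "all_unrooted_binary_trees",
    "brute_force_optima",
    "random_unrooted_tree",
    "nni_perturb",
    "generate_fixture",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic instance; the seed fully determines it."""

    n: int = 6
    k: int = 4
    retention: float = 0.7
    nni: int = 1
    seed: int = 0
    constraint_perturbed: int = 2
    constraint_nni: int = 1

    def __post_init__(self):
        if self.n < 4:
            raise ValueError("need at least 4 taxa")
        if not (0 < self.retention <= 1):
            raise ValueError("retention must be in (0, 1]")
        if self.k < 1:
            raise ValueError("need at least one source tree")


# ---------------------------------------------------------------------------
# Exhaustive enumeration (the anti-drift oracle)
# ---------------------------------------------------------------------------

def all_unrooted_binary_trees(taxa: TaxonIndex) -> Iterator[Tree]:
    """Every unrooted binary topology on the taxon set, exactly once
    ((2n-5)!! of them), by inserting taxa one at a time into every edge."""
    n = taxa.n
    if not (4 <= n <= 10):
        raise ValueError("exhaustive enumeration supported for 4 <= n <= 10")

    def expand(tree: Node, next_taxon: int) -> Iterator[Node]:
        if next_taxon == n:
            yield tree
            return
        leaf_label = taxa.labels[next_taxon]
        for edge_id in range(_count_edges(tree)):
            grown = _insert_at_edge(tree, edge_id, leaf_label)
            yield from expand(grown, next_taxon + 1)

    base = Node(children=[Node(label=taxa.labels[0]),
                          Node(label=taxa.labels[1]),
                          Node(label=taxa.labels[2])])
    for t in expand(base, 3):
        yield Tree(t.copy(), rooted=False)


def _count_edges(root: Node) -> int:
    # edges of the unrooted representation = #nodes - 1 (root excluded)
    count = 0
    stack = list(root.children)
    while stack:
        node = stack.pop()
        count += 1
        stack.extend(node.children)
    return count


def _insert_at_edge(root: Node, edge_id: int, label: str) -> Node:
    """Copy of the tree with a new leaf attached in the middle of the
    ``edge_id``-th edge (preorder over non-root nodes)."""
    counter = [0]

    def rebuild(node: Node, is_root: bool) -> Node:
        if is_root:
            return Node(children=[rebuild(c, False) for c in node.children])
        my_id = counter[0]
        counter[0] += 1
        if node.is_leaf:
            copied = Node(label=node.label)
        else:
            copied = Node(children=[rebuild(c, False) for c in node.children])
        if my_id == edge_id:
            return Node(children=[copied, Node(label=label)])
        return copied

    return rebuild(root, True)


def brute_force_optima(cs: ConstraintSet, scorer: TripartitionScorer):
    """Filter all unrooted binary trees to those whose bipartitions are all
    allowed, score each with the DIRECT tree scorer, and return
    ``(best_score, optimal_trees)``; ``(None, [])`` when no tree is feasible.
    """
    taxa = cs.taxa
    if taxa.n > 8:
        raise ValueError("brute force limited to n <= 8")
    maximize = scorer.direction == "max"
    best: Optional[int] = None
    optima: list[Tree] = []
    for tree in all_unrooted_binary_trees(taxa):
        if not bipartitions_of(tree, taxa) <= cs.X:
            continue
        score = scorer.tree_score(tree)
        if best is None or (score > best if maximize else score < best):
            best = score
            optima = [tree]
        elif score == best:
            optima.append(tree)
    return best, optima


# ---------------------------------------------------------------------------
# Random trees and perturbations
# ---------------------------------------------------------------------------

def random_unrooted_tree(taxa: TaxonIndex, rng: random.Random,
                         model: str = "uniform") -> Tree:
    """A random unrooted binary tree: ``uniform`` inserts each taxon at an
    edge chosen uniformly at random, which samples labeled topologies
    uniformly; ``yule`` grows by splitting a uniformly chosen pendant edge."""
    n = taxa.n
    root = Node(children=[Node(label=taxa.labels[0]),
                          Node(label=taxa.labels[1]),
                          Node(label=taxa.labels[2])])
    for i in range(3, n):
        if model == "uniform":
            edge_id = rng.randrange(_count_edges(root))
        elif model == "yule":
            edge_id = _random_pendant_edge(root, rng)
        else:
            raise ValueError(f"unknown tree model {model!r}")
        root = _insert_at_edge(root, edge_id, taxa.labels[i])
    return Tree(root, rooted=False)


def _random_pendant_edge(root: Node, rng: random.Random) -> int:
    pendant = []
    counter = [0]

    def walk(node: Node, is_root: bool):
        if not is_root:
            my_id = counter[0]
            counter[0] += 1
            if node.is_leaf:
                pendant.append(my_id)
        for c in node.children:
            walk(c, False)

    walk(root, True)
    return rng.choice(pendant)


def nni_perturb(tree: Tree, taxa: TaxonIndex, moves: int,
                rng: random.Random) -> Tree:
    """Apply ``moves`` nearest-neighbor-interchange moves, each at an
    internal edge chosen uniformly, with the swapped subtree pair chosen
    uniformly among the two options."""
    from .trees import bipartitions_of as bips, root_at_edge

    current = tree
    for _ in range(moves):
        internal = sorted(bips(current, taxa))
        if not internal:
            return current  # no internal edges (n < 4 after restriction)
        bip = rng.choice(internal)
        rooted = root_at_edge(current, bip, taxa)
        left, right = rooted.root.children
        if left.is_leaf or right.is_leaf:
            continue
        i = rng.randrange(2)
        j = rng.randrange(2)
        left.children[i], right.children[j] = \
            right.children[j], left.children[i]
        current = unroot(rooted)
    return current


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def generate_fixture(spec: FixtureSpec, taxa: Optional[TaxonIndex] = None,
                     model: str = "uniform"):
    """Build ``(model_tree, sources, constraint_trees)`` for a spec.

    The model tree is drawn at random; each of the k source trees restricts
    the model to a random leaf subset (ceil(retention * n), at least 4) and
    applies the specified number of NNI moves; the constraint trees are the
    model tree plus ``constraint_perturbed`` NNI-perturbed complete copies,
    which makes score ties possible.  Everything is reproducible from the
    seed.
    """
    if taxa is None:
        taxa = TaxonIndex(f"t{i}" for i in range(spec.n))
    if taxa.n != spec.n:
        raise ValueError("taxon index size does not match fixture spec")
    rng = random.Random(spec.seed)
    model_tree = random_unrooted_tree(taxa, rng, model=model)

    subset_size = max(4, round(spec.retention * spec.n))
    if subset_size > spec.n:
        subset_size = spec.n
    sources: list[Tree] = []
    for _ in range(spec.k):
        keep = rng.sample(range(spec.n), subset_size)
        mask = 0
        for i in keep:
            mask |= 1 << i
        src = restrict(model_tree, mask, taxa)
        src = nni_perturb(src, taxa, spec.nni, rng)
        sources.append(src)

    constraints = [model_tree]
    for _ in range(spec.constraint_perturbed):
        constraints.append(nni_perturb(model_tree, taxa,
                                       spec.constraint_nni, rng))
    return model_tree, SourceTreeSet(sources, taxa), constraints
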