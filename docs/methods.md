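# Methods

## Search space

The input is a set of source trees (leaf sets may be proper subsets of the
taxon set *S*, polytomies allowed, ≥ 4 leaves each) and a set of
*constraint trees*, each complete on *S*.  The allowed-bipartition set *X*
is the union of the constraint trees' non-trivial bipartitions; an
augmentation file can add further bipartitions.  The allowed-clade set
contains both halves of every bipartition in *X*, the full set *S*, every
singleton, and every singleton's complement.  The singleton complements
deserve a note: they are the sides of trivial bipartitions, present in
every tree, and including them makes *every* rooting of every feasible
tree — pendant-edge rootings included — representable in the DP.  That is
what makes the rooted optimum count exactly (2n−3) times the unrooted
count, which the counting analytics rely on (and enforce by an exact
divisibility check).  Without them the clade set would be smaller
(2|X| + n + 1 instead of 2|X| + 2n + 1) but the rooted/unrooted accounting
would not close.

Constraint trees must be complete because the feasibility guarantee comes
from them: a complete binary constraint tree is itself a feasible
solution.  If no binary constraint tree is supplied, a warning is issued
and infeasibility — a clade on every root path with no allowed split — is
reported with a witness clade.  Deriving allowed bipartitions from
incomplete source trees is deliberately out of scope; users supply
complete trees produced by whatever estimation methods they prefer.

## Criteria and the weight decomposition

Both built-in criteria are integer counts, maximized:

* **rfs** (Robinson–Foulds supertree): F(T) = Σᵢ |C(T|_{Lᵢ}) ∩ C(tᵢ)|,
  restriction to each source tree's own leaf set, each *distinct* induced
  bipartition counted once, trivial induced bipartitions not counted.
  The total RF distance Σᵢ [|C(tᵢ)| + |C(T|_{Lᵢ})| − 2·sharedᵢ] is the
  minimized companion quantity.
* **quartet**: F(T) = Σ_g #{4-subsets q ⊆ L_g : T|_q and g|_q have the
  same resolved topology}.  Quartets unresolved in a polytomous gene tree
  contribute nothing; incomplete gene trees are scored only over their own
  leaves.

The DP needs per-tripartition weights satisfying the rooting-invariant
sum contract (see README).  The decomposition used here anchors each
shared bipartition at a unique node of the rooted tree.  For one source
tree with leaf set L, write a = A∩L, b = B∩L, c = C∩L at tripartition
(A, B, C).  A non-trivial source bipartition P|Q is induced by T|_L
exactly when P (or Q) is a clade of the restricted rooted tree, and the
*minimal* tree clade intersecting L in P is the unique node where both
child clades meet L.  Hence the positive term counts source blocks equal
to a ∪ b with a, b both non-empty.  When both P and Q are restricted
clades (the restricted root joins them), the bipartition is anchored
twice; this happens at the unique node with c = ∅ and a, b non-empty,
where a|b is itself a source bipartition, giving the correction term

    w(A,B,C) = Σ_sources ( [a≠∅, b≠∅, a∪b ∈ blocks] − [c=∅, a≠∅, b≠∅, a ∈ blocks] ).

The quartet weight is the same decomposition applied to every 4-leaf
restriction of every gene tree, reduced to bitmask pattern counts over the
gene's precomputed resolved quartets.  Individual weights may be negative;
only sums over complete rootings are meaningful.  The decomposition is not
assumed correct — it is *verified*: the test suite checks the weight sum
against the independent direct scorers exhaustively over all 105 six-taxon
topologies, under every rooting, for both criteria, and on random 5–7
taxon instances against brute-force enumeration.  The direct scorers never
touch tripartitions, keeping the two computation paths independent.

All scores and weights are exact integers and all frequencies exact
rationals; there is no floating point anywhere in the DP or the counting,
because tie detection by exact equality is the entire point.

## DP and the all-optima DAG

Clades are processed in (size, numeric value) order; evaluation order and
all tie-breaks are deterministic, so identical inputs give identical
outputs.  For each clade every optimal split is stored, yielding a DAG
whose paths from *S* generate exactly the optimal rooted trees.
Per-clade subtree counts are computed lazily in arbitrary precision.
Weights are memoized per canonical tripartition ((A,B,C) ≡ (B,A,C), the
numerically smaller clade stored first).

Analytics on the DAG:

* counting — rooted count at *S*; unrooted count by exact division by
  2n−3 (an inexact division raises, as it would indicate a
  rooting-variant scorer);
* bipartition frequencies — a bipartition c|S∖c occurs in
  optsubtrees(c)·optsubtrees(S∖c) of the unrooted optima (the rooted
  optima rooted on that edge map one-to-one onto the unrooted optima
  containing the edge); the frequency is that product over the unrooted
  count.  The frequency is deliberately defined over *unrooted* optima —
  defining it as a fraction of rooted optima would scale every value by
  1/(2n−3) and break the consensus semantics;
* enumeration — depth-first generation of rooted optima, deduplicated to
  unrooted topologies by a canonical form (deterministic newick of the
  rooting at the lowest-indexed taxon's pendant edge);
* sampling — top-down, choosing each split with probability proportional
  to its optimal-combination count: uniform over rooted optima, hence
  uniform over unrooted optima (each has exactly 2n−3 rooted
  representatives).  Uniformity is a design choice, validated by a
  chi-square test;
* consensus — strict (frequency = 1), majority (> 1/2), greedy (all
  bipartitions in descending frequency, skipping incompatible ones), and
  α-consensus (> α; for α < 1/2 the accepted set may be incompatible, so
  greedy insertion is applied to it).  Frequency ties in greedy insertion
  are broken by canonical clade order — the same order used when
  extracting a single optimal tree — and this is documented as arbitrary,
  since the greedy consensus is not unique in general;
* corrected support — the support of a branch is its frequency across the
  optimal set (absent ⇒ 0); with raw per-branch supports supplied, the
  corrected value is raw × frequency.  This product form is an
  approximation to averaging per-tree supports across optima, exact when
  the raw support of a branch is the same in every optimum containing it;
  exact averaging would require annotating every optimum;
* MCC heuristic — greedy consensus ranked by corrected support, annotated
  with those values (finding the true maximum-credibility tree is
  NP-hard);
* error metrics — FN and FP bipartition counts against a binary model
  tree, normalized by n−3, their average, and F1 (harmonic mean of
  precision and recall; defined as 0 when no bipartition is shared, e.g.
  a star estimate, which scores FN = 1, FP = 0).

## Synthetic fixtures

`generate_fixture` emulates the structure of supertree/phylogenomic
inputs without simulating evolution: a model tree (uniform over labeled
topologies by default; Yule optional), k source trees obtained by
restricting the model to a random leaf subset (⌈retention·n⌉, minimum 4)
and applying a number of NNI moves, and a constraint set consisting of
the model tree plus NNI-perturbed complete copies, whose conflicting
bipartitions are what create score ties.  Defaults (n = 6, k = 4,
retention = 0.7, 1 NNI move, 2 perturbed constraint trees) give small
instances with frequent ties — a regime chosen because exhaustive
verification is possible there.  Everything is reproducible from the
seed.

These fixtures do **not** model coalescent gene-tree discordance, branch
lengths, estimation error from sequences, or realistic taxon sampling;
passing tests demonstrate algorithmic correctness (exact agreement with
enumeration) and the direction of consensus trade-offs, not field
accuracy on real data.  In particular, at these sizes the strict
consensus's FN increase can outweigh its FP decrease on average, whereas
the per-instance inequalities (FP never worse, FN never better than a
single optimum) hold always and are what the tests assert.

## Problem sizes

Exhaustive cross-checks use 5–7 taxa (15–945 topologies), where the full
tree space is enumerable in seconds; the weight-contract check covers all
105 six-taxon topologies under all 9 rootings for 20 source sets per
criterion; sampling uniformity uses 10⁴ draws.  These sizes make the
entire verification suite run in well under a minute while leaving every
check exact rather than sampled.

## Known limitations

* Constraint sets must come from complete trees; no repair is attempted
  when the allowed set admits no binary tree.
* Only the two built-in criteria are provided; the scorer interface
  (weight + direct score + bounds) is the extension point for other
  members of this DP family.
* The DP is quadratic in the number of allowed clades per level through
  the split scan, and enumeration cost is proportional to the number of
  optima; counts, frequencies, and consensus remain cheap even when the
  optimum count is astronomically large.
* Posterior-probability branch supports are not computed; raw supports
  are injected by the user when available.
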