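# siesta

Constrained exact supertree and species-tree estimation that keeps **all**
optimal trees, not just one.

## The problem

Supertree methods combine trees on overlapping subsets of a taxon set *S*
into one tree on all of *S*; summary methods for phylogenomics combine gene
trees — which disagree with the species tree through estimation error or
incomplete lineage sorting — into a species-tree estimate.  Both lead to
NP-hard optimization problems.  A practical route to exact solutions is
*constrained* optimization: fix a set *X* of allowed bipartitions (taken
from trees built by other methods), and search only trees *T* with
C(T) ⊆ X, where C(T) is the bipartition set of *T*.  Within that space,
dynamic programming over the allowed clades (the halves of the bipartitions
in *X*) finds a provably optimal tree in polynomial time.

Such optimizations frequently have **many** co-optimal trees — counts like
10⁹² on real supertree datasets are possible — and reporting a single
arbitrary optimum both hides that uncertainty and inflates branch support.
This package runs the constrained DP while recording *every* optimal
choice, producing a DAG that compactly represents the entire optimal set,
and then answers questions about that set exactly.

## Criteria

Two classic integer-valued criteria are built in (both maximized):

* `rfs` — the Robinson–Foulds supertree criterion: maximize
  Σᵢ |C(T|_{Lᵢ}) ∩ C(tᵢ)|, the number of source-tree bipartitions shared
  with *T* restricted to each source tree's leaf set Lᵢ (equivalently,
  minimize the total RF distance, also reported).
* `quartet` — the quartet-agreement criterion used for species-tree
  estimation under incomplete lineage sorting: maximize the number of
  gene-tree quartet topologies that agree with *T*.

Each criterion is a tripartition weight *w* with the defining property
that, for any complete binary tree *T* on *S* and any rooting *Tʳ*,

    F(T) = Σ_{t ∈ trips(Tʳ)} w(t)

where trips(*Tʳ*) are the (A, B, C) tripartitions at the internal nodes of
*Tʳ*.  The DP recursion over allowed clades c is

    f(c) = max { f(a) + f(b) + w(a, b, S∖c) :  a ⊎ b = c, a, b allowed },

with f = 0 on singletons and f(S) the optimal score.  Every split pair
(a, b) attaining f(c) is recorded, and the per-clade counts
optsubtrees(c) = Σ optsubtrees(a)·optsubtrees(b) over recorded splits give
exact (arbitrary-precision) optimum counts.  The rooted-tree count divides
exactly by 2n−3 to give the unrooted count, and the fraction of optima
containing a bipartition c|S∖c is optsubtrees(c)·optsubtrees(S∖c) divided
by the unrooted count — computed as exact rationals.

On top of the DAG the package provides: counting, full enumeration,
uniform random sampling, strict / majority / greedy / α consensus trees,
branch-support correction (raw support × fraction of optima containing the
branch), a greedy maximum-clade-credibility tree, and FN/FP/F1 error
metrics against a model tree.

## Worked example

The smallest instance with a tie: two conflicting 4-taxon source trees,
both also serving as the constraint set.

```sh
printf '((a,b),(c,d));\n((a,c),(b,d));\n' > sources.nwk
cp sources.nwk constraints.nwk
siesta count --criterion rfs --sources sources.nwk --constraint-trees constraints.nwk
```

```
taxa: 4
|X|: 2
allowed clades: 13
splits: 18
optimal score f(S): 1
rooted optima: 10
unrooted optima: 2
```

Any tree shares exactly one bipartition with one source and zero with the
other, so the optimal score is 1 and **both** source topologies are optimal
(2 unrooted optima; 10 = 2 × (2·4−3) rootings).  The analytics make the
tie explicit:

```sh
siesta enumerate --sources sources.nwk --constraint-trees constraints.nwk
# (a,b,(c,d));
# (a,(b,d),c);
siesta consensus --kind strict ...   # (a,b,c,d);   — the tie collapses to a star
siesta mcc ...                       # (a,b,(c,d)0.500000);
```

The strict consensus keeps only branches present in *every* optimum (none,
here).  The MCC tree resolves the topology but annotates the internal
branch with corrected support 0.5: it appears in exactly half of the
optimal trees, so no single-tree support above 0.5 would be justified.

Other subcommands: `search` (one optimal tree), `sample --seed N`
(uniform draws), `annotate --tree F` (corrected support on a given tree),
`fixture` (synthetic instances), `score` (direct criterion score),
`--save-dag/--load-dag` (reuse one search across analytics).

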