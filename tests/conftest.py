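import pytest

from siesta import (
    SourceTreeSet,
    TaxonIndex,
    build_constraint_set,
    enumerate_splits,
    make_scorer,
    parse_newick,
    restrict,
    run_dp,
)
from siesta.oracle_synth import all_unrooted_binary_trees


@pytest.fixture
def taxa4():
    return TaxonIndex("abcd")


@pytest.fixture
def taxa6():
    return TaxonIndex("abcdef")


@pytest.fixture(scope="session")
def trees6():
    """All 105 unrooted binary topologies on 6 taxa (session-cached)."""
    taxa = TaxonIndex("abcdef")
    return taxa, list(all_unrooted_binary_trees(taxa))


@pytest.fixture
def tie4(taxa4):
    """The canonical 4-taxon tie: sources {ab|cd, ac|bd}, X = both."""
    t1 = parse_newick("((a,b),(c,d));")
    t2 = parse_newick("((a,c),(b,d));")
    src = SourceTreeSet([t1, t2], taxa4)
    cs = build_constraint_set([t1, t2], taxa4)
    table = enumerate_splits(cs)
    dag = run_dp(table, make_scorer("rfs", src))
    return taxa4, src, cs, dag


def random_source_set(taxa, pool, rng, k=3, min_leaves=4):
    """Random (possibly incomplete) source trees drawn from a topology pool."""
    srcs = []
    for t in rng.sample(pool, k):
        size = rng.randint(min_leaves, taxa.n)
        keep = rng.sample(range(taxa.n), size)
        srcs.append(restrict(t, sum(1 << i for i in keep), taxa))
    return SourceTreeSet(srcs, taxa)
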