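"""Counting, frequencies, enumeration, sampling, consensus, corrected
support, the MCC heuristic, and error metrics."""

import random
from fractions import Fraction

import pytest

from siesta import (
    Bipartition,
    SourceTreeSet,
    TaxonIndex,
    TreeError,
    bipartitions_of,
    build_constraint_set,
    canonical_form,
    enumerate_splits,
    make_scorer,
    parse_newick,
    run_dp,
    write_newick,
)
from siesta.analytics import (
    bipartition_frequencies,
    consensus,
    corrected_support,
    count_rooted_optima,
    count_unrooted_optima,
    enumerate_optimal_trees,
    mcc_tree,
    sample_optimal_tree,
    tree_error_rates,
)
from siesta.oracle_synth import (
    FixtureSpec,
    brute_force_optima,
    generate_fixture,
    random_unrooted_tree,
)


def dag_for(constraints, src, criterion="rfs"):
    cs = build_constraint_set(constraints, src.taxa)
    return cs, run_dp(enumerate_splits(cs), make_scorer(criterion, src))


def single_tree_dag(n=6, seed=1):
    taxa = TaxonIndex(f"t{i}" for i in range(n))
    tree = random_unrooted_tree(taxa, random.Random(seed))
    src = SourceTreeSet([tree.copy()], taxa)
    _, dag = dag_for([tree], src)
    return taxa, tree, dag


class TestCounting:
    def test_single_tree_counts(self):
        taxa, tree, dag = single_tree_dag()
        assert count_rooted_optima(dag) == 2 * taxa.n - 3
        assert count_unrooted_optima(dag) == 1

    def test_tie_counts(self, tie4):
        taxa, src, cs, dag = tie4
        assert count_rooted_optima(dag) == 10
        assert count_unrooted_optima(dag) == 2

    @pytest.mark.parametrize("criterion", ["rfs", "quartet"])
    def test_counts_match_brute_force(self, criterion):
        for seed in range(8):
            spec = FixtureSpec(n=6, k=3, retention=0.8, nni=1, seed=seed)
            _, src, constraints = generate_fixture(spec)
            cs, dag = dag_for(constraints, src, criterion)
            _, optima = brute_force_optima(cs, make_scorer(criterion, src))
            assert count_unrooted_optima(dag) == len(optima)


class TestFrequencies:
    def test_single_tree_all_frequencies_one(self):
        taxa, tree, dag = single_tree_dag()
        freqs = bipartition_frequencies(dag)
        assert set(freqs.frequencies) == bipartitions_of(tree, taxa)
        assert all(v == 1 for _, v in freqs.items())

    def test_tie_frequencies_are_half(self, tie4):
        taxa, src, cs, dag = tie4
        freqs = bipartition_frequencies(dag)
        m = taxa.mask_of
        full = taxa.full_mask
        assert freqs.frequencies == {
            Bipartition(m("ab"), full): Fraction(1, 2),
            Bipartition(m("ac"), full): Fraction(1, 2),
        }

    @pytest.mark.parametrize("criterion", ["rfs", "quartet"])
    def test_frequencies_match_empirical_over_optimal_set(self, criterion):
        for seed in range(6):
            spec = FixtureSpec(n=6, k=3, retention=0.7, nni=1, seed=seed)
            _, src, constraints = generate_fixture(spec)
            taxa = src.taxa
            cs, dag = dag_for(constraints, src, criterion)
            _, optima = brute_force_optima(cs, make_scorer(criterion, src))
            empirical: dict = {}
            for t in optima:
                for bip in bipartitions_of(t, taxa):
                    empirical[bip] = empirical.get(bip, 0) + 1
            expected = {b: Fraction(c, len(optima))
                        for b, c in empirical.items()}
            assert bipartition_frequencies(dag).frequencies == expected


class TestEnumerationAndSampling:
    def test_tie_enumeration_is_exactly_both_trees(self, tie4):
        taxa, src, cs, dag = tie4
        got = {canonical_form(t, taxa) for t in enumerate_optimal_trees(dag)}
        want = {canonical_form(parse_newick("((a,b),(c,d));"), taxa),
                canonical_form(parse_newick("((a,c),(b,d));"), taxa)}
        assert got == want

    def test_limit_truncates_deterministically(self, tie4):
        taxa, src, cs, dag = tie4
        first = list(enumerate_optimal_trees(dag, limit=1))
        assert len(first) == 1
        assert write_newick(first[0], taxa) == \
            write_newick(next(enumerate_optimal_trees(dag)), taxa)

    def test_sampling_reproducible_and_optimal(self, tie4):
        taxa, src, cs, dag = tie4
        t1 = sample_optimal_tree(dag, seed=5)
        t2 = sample_optimal_tree(dag, seed=5)
        assert write_newick(t1, taxa) == write_newick(t2, taxa)
        scorer = make_scorer("rfs", src)
        assert scorer.tree_score(t1) == dag.optimal_score

    def test_single_optimum_always_sampled(self):
        taxa, tree, dag = single_tree_dag()
        for seed in range(5):
            assert canonical_form(sample_optimal_tree(dag, seed), taxa) == \
                canonical_form(tree, taxa)


class TestConsensus:
    def test_tie_strict_and_majority_are_star(self, tie4):
        taxa, src, cs, dag = tie4
        assert write_newick(consensus(dag, "strict"), taxa) == "(a,b,c,d);"
        assert write_newick(consensus(dag, "majority"), taxa) == "(a,b,c,d);"

    def test_tie_greedy_breaks_tie_canonically(self, tie4):
        taxa, src, cs, dag = tie4
        assert write_newick(consensus(dag, "greedy"), taxa) == "(a,b,(c,d));"

    def test_single_optimum_all_kinds_equal_the_tree(self):
        taxa, tree, dag = single_tree_dag()
        want = canonical_form(tree, taxa)
        for kind in ("strict", "majority", "greedy"):
            assert canonical_form(consensus(dag, kind), taxa) == want

    def test_alpha_half_equals_majority(self):
        for seed in range(5):
            spec = FixtureSpec(n=6, k=3, retention=0.7, nni=1, seed=seed)
            _, src, constraints = generate_fixture(spec)
            _, dag = dag_for(constraints, src)
            a = write_newick(consensus(dag, "alpha", alpha=Fraction(1, 2)),
                             src.taxa)
            b = write_newick(consensus(dag, "majority"), src.taxa)
            assert a == b

    def test_refinement_law(self):
        """strict ⊆ majority ⊆ greedy as bipartition sets."""
        taxa_cache = {}
        for seed in range(20):
            spec = FixtureSpec(n=7, k=3, retention=0.7, nni=2, seed=seed)
            _, src, constraints = generate_fixture(spec)
            taxa = src.taxa
            _, dag = dag_for(constraints, src)
            strict = bipartitions_of(consensus(dag, "strict"), taxa)
            majority = bipartitions_of(consensus(dag, "majority"), taxa)
            greedy = bipartitions_of(consensus(dag, "greedy"), taxa)
            assert strict <= majority <= greedy

    def test_alpha_out_of_range_rejected(self, tie4):
        *_, dag = tie4
        with pytest.raises(ValueError):
            consensus(dag, "alpha", alpha=Fraction(3, 2))
        with pytest.raises(ValueError):
            consensus(dag, "alpha")


class TestCorrectedSupport:
    def test_bipartition_in_all_optima_keeps_full_support(self):
        taxa, tree, dag = single_tree_dag()
        support = corrected_support(tree, dag)
        assert all(v == 1 for v in support.values())

    def test_split_in_one_of_two_optima_is_halved(self, tie4):
        taxa, src, cs, dag = tie4
        tree = parse_newick("((a,b),(c,d));")
        bip = Bipartition(taxa.mask_of("ab"), taxa.full_mask)
        assert corrected_support(tree, dag)[bip] == Fraction(1, 2)
        raw = {bip: Fraction(9, 10)}
        assert corrected_support(tree, dag, base_support=raw)[bip] == \
            Fraction(9, 20)

    def test_absent_split_gets_zero(self, tie4):
        taxa, src, cs, dag = tie4
        tree = parse_newick("((a,d),(b,c));")
        bip = Bipartition(taxa.mask_of("ad"), taxa.full_mask)
        assert corrected_support(tree, dag)[bip] == 0


class TestMCC:
    def test_single_optimum_is_the_tree_with_unit_support(self):
        taxa, tree, dag = single_tree_dag()
        mcc, values = mcc_tree(dag)
        assert canonical_form(mcc, taxa) == canonical_form(tree, taxa)
        assert all(v == 1 for v in values.values())

    def test_tie_mcc_topology_and_support(self, tie4):
        taxa, src, cs, dag = tie4
        mcc, values = mcc_tree(dag)
        assert write_newick(mcc, taxa, support=values) == \
            "(a,b,(c,d)0.500000);"

    def test_base_support_can_reorder_the_ranking(self, tie4):
        taxa, src, cs, dag = tie4
        ab = Bipartition(taxa.mask_of("ab"), taxa.full_mask)
        ac = Bipartition(taxa.mask_of("ac"), taxa.full_mask)
        # both optima have frequency 1/2; a raw support favoring ac|bd
        # must flip the greedy choice
        raw = {ab: Fraction(1, 10), ac: Fraction(9, 10)}
        mcc, values = mcc_tree(dag, base_support=raw)
        assert ac in values and ab not in values


class TestErrorRates:
    def test_identical_trees_have_zero_error(self, taxa6):
        tree = parse_newick("((a,b),((c,d),(e,f)));")
        rep = tree_error_rates(tree, tree, taxa6)
        assert (rep.fn, rep.fp, rep.average, rep.f1) == (0, 0, 0, 1)

    def test_star_estimate_is_pure_false_negative(self):
        taxa = TaxonIndex(f"t{i}" for i in range(10))
        model = random_unrooted_tree(taxa, random.Random(0))
        star = parse_newick("(" + ",".join(taxa.labels) + ");")
        rep = tree_error_rates(star, model, taxa)
        assert rep.fn == 1 and rep.fp == 0 and rep.average == Fraction(1, 2)

    def test_single_nni_costs_one_third_on_six_taxa(self, taxa6):
        model = parse_newick("((a,b),((c,d),(e,f)));")
        # one NNI at the cd|abef edge: c swapped with the (e,f) subtree
        est = parse_newick("(((a,b),c),(d,(e,f)));")
        rep = tree_error_rates(est, model, taxa6)
        assert rep.fn == rep.fp == Fraction(1, 3)

    def test_leaf_set_mismatch_rejected(self, taxa6):
        model = parse_newick("((a,b),((c,d),(e,f)));")
        est = parse_newick("((a,b),(c,d));")
        with pytest.raises(TreeError, match="leaf set"):
            tree_error_rates(est, model, taxa6)
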