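"""Heuristic search: rearrangements, ratchet/drift, multistart, consensus,
bootstrap, tree-collection closure."""

from fractions import Fraction

import numpy as np
import pytest

from depclad import (
    Character,
    CharacterMatrix,
    EW,
    ParsimonyScorer,
    PhyloTree,
    SearchConfig,
    SimulationConfig,
    TreeCollection,
    bootstrap_support,
    enumerate_topologies,
    multistart_search,
    nni_neighbors,
    random_addition_tree,
    ratchet,
    simulate_matrix,
    spr_neighbors,
    strict_consensus,
    swap_to_local_optimum,
    tbr_neighbors,
    update_tree_collection,
)

from conftest import perfect_matrix, random_topology


@pytest.fixture
def clean_case(rng):
    taxa = [f"t{i}" for i in range(7)]
    true = random_topology(rng, taxa)
    matrix = perfect_matrix(true, copies=2)
    return matrix, true


class TestNeighbourhoods:
    def test_counts_and_nesting(self, six_taxon_tree):
        t = six_taxon_tree
        nni = set(nni_neighbors(t))
        spr = set(spr_neighbors(t))
        tbr = set(tbr_neighbors(t))
        assert len(nni) == 2 * len(t.internal_edges())
        assert nni <= spr <= tbr | {t}
        assert all(nb.leaf_set == t.leaf_set for nb in tbr)
        assert all(nb.is_binary for nb in tbr)

    def test_optimum_quality_orders_with_neighbourhood(self, clean_case, rng):
        matrix, _ = clean_case
        scorer = ParsimonyScorer(matrix)
        start = random_topology(rng, matrix.taxon_labels)
        s_nni = swap_to_local_optimum(start, scorer, "NNI").score
        s_spr = swap_to_local_optimum(start, scorer, "SPR").score
        s_tbr = swap_to_local_optimum(start, scorer, "TBR").score
        assert s_nni >= s_spr >= s_tbr


class TestRandomAddition:
    def test_deterministic_for_seed(self, clean_case):
        matrix, _ = clean_case
        scorer = ParsimonyScorer(matrix)
        assert random_addition_tree(matrix, scorer, 99) == \
            random_addition_tree(matrix, scorer, 99)

    def test_four_taxa_picks_best_topology(self):
        taxa = ["A", "B", "C", "D"]
        chars = [Character(i, state_codes=(0, 1)) for i in range(2)]
        cells = [[1, 1], [1, 1], [0, 0], [0, 0]]
        m = CharacterMatrix(taxa, chars, cells)
        scorer = ParsimonyScorer(m)
        t = random_addition_tree(m, scorer, 0)
        assert t == PhyloTree.from_newick("((A,B),(C,D));")

    def test_too_few_taxa(self):
        m = CharacterMatrix(["a", "b", "c"],
                            [Character(0)], [[0], [0], [1]])
        with pytest.raises(ValueError, match="4 taxa"):
            random_addition_tree(m, ParsimonyScorer(m), 0)

    def test_clean_matrix_ras_is_already_optimal(self, clean_case):
        matrix, true = clean_case
        scorer = ParsimonyScorer(matrix)
        t = random_addition_tree(matrix, scorer, 3)
        assert scorer.total(t) == scorer.total(true)


class TestSwap:
    @pytest.mark.parametrize("seed", [2, 8])
    def test_tbr_reaches_exhaustive_optimum(self, seed):
        matrix, graph, _ = simulate_matrix(
            SimulationConfig(n_taxa=6, n_characters=15, rng_seed=seed)
        )
        scorer = ParsimonyScorer(matrix, graph)
        best = min(scorer.total(t)
                   for t in enumerate_topologies(matrix.taxon_labels))
        rng = np.random.default_rng(seed)
        start = random_topology(rng, matrix.taxon_labels)
        result = swap_to_local_optimum(start, scorer, "TBR")
        assert result.score == best

    def test_optimal_tree_unchanged(self, clean_case):
        matrix, true = clean_case
        scorer = ParsimonyScorer(matrix)
        result = swap_to_local_optimum(true, scorer, "TBR")
        assert result.tree == true
        assert result.score == scorer.total(true)


class TestRatchet:
    def test_zero_iterations_returns_input(self, clean_case):
        matrix, true = clean_case
        scorer = ParsimonyScorer(matrix)
        assert ratchet(true, matrix, scorer, 0, seed=1) == [true]

    def test_seeded_reproducibility(self, rng):
        matrix, graph, _ = simulate_matrix(
            SimulationConfig(n_taxa=6, n_characters=15, rng_seed=4)
        )
        scorer = ParsimonyScorer(matrix, graph)
        start = random_topology(rng, matrix.taxon_labels)
        a = ratchet(start, matrix, scorer, 4, seed=7, swap_mode="NNI")
        b = ratchet(start, matrix, scorer, 4, seed=7, swap_mode="NNI")
        assert a == b

    def test_ratchet_escapes_nni_optima(self):
        """From NNI-trapped starts, a short SPR ratchet reaches the global
        (exhaustively verified) optimum on at least 9 of 10 seeds."""
        hits = 0
        seeds = range(10)
        for seed in seeds:
            matrix, graph, _ = simulate_matrix(
                SimulationConfig(n_taxa=7, n_characters=18, rng_seed=100 + seed)
            )
            scorer = ParsimonyScorer(matrix, graph)
            best = min(scorer.total(t)
                       for t in enumerate_topologies(matrix.taxon_labels))
            rng = np.random.default_rng(seed)
            start = swap_to_local_optimum(
                random_topology(rng, matrix.taxon_labels), scorer, "NNI"
            ).tree
            found = ratchet(start, matrix, scorer, 15, seed=seed,
                            swap_mode="SPR")
            if min(scorer.total(t) for t in found) == best:
                hits += 1
        assert hits >= 9


class TestMultistart:
    def test_clean_matrix_unique_mpt_is_true_tree(self, clean_case):
        matrix, true = clean_case
        cfg = SearchConfig(replicates=3, hits_required=2,
                           ratchet_iterations=0, drift_iterations=0,
                           rng_seed=11)
        result = multistart_search(matrix, None, EW, cfg)
        assert result.trees == [true]

    def test_single_replicate_equals_ras_plus_swap(self, clean_case):
        matrix, _ = clean_case
        scorer = ParsimonyScorer(matrix)
        cfg = SearchConfig(replicates=1, hits_required=1,
                           ratchet_iterations=0, drift_iterations=0,
                           rng_seed=5, collapse_rule="none")
        result = multistart_search(matrix, None, EW, cfg)
        rng = np.random.default_rng(5)
        seed0 = int(rng.integers(2**31 - 1))
        manual = swap_to_local_optimum(
            random_addition_tree(matrix, scorer, seed0), scorer, "TBR"
        )
        assert result.score == manual.score
        assert set(result.trees) == set(manual.all_best)

    def test_two_island_matrix_returns_both(self):
        """Two symmetric blocks of conflicting characters create two equally
        parsimonious topologies; both must be found."""
        taxa = list("ABCDEF")
        t1 = PhyloTree.from_newick("(((A,B),C),((D,E),F));")
        t2 = PhyloTree.from_newick("(((A,C),B),((D,F),E));")
        cols = []
        for bip in sorted(t1.bipartitions, key=sorted):
            cols.append({t: int(t in bip) for t in taxa})
        for bip in sorted(t2.bipartitions, key=sorted):
            cols.append({t: int(t in bip) for t in taxa})
        chars = [Character(i, state_codes=(0, 1)) for i in range(len(cols))]
        m = CharacterMatrix(taxa, chars,
                            [[c[t] for c in cols] for t in taxa])
        scorer = ParsimonyScorer(m)
        # brute force confirms the tie and the optimum
        scores = {t: scorer.total(t) for t in enumerate_topologies(taxa)}
        best = min(scores.values())
        best_trees = {t for t, s in scores.items() if s == best}
        assert {t1, t2} <= best_trees
        cfg = SearchConfig(replicates=8, hits_required=8,
                           ratchet_iterations=0, drift_iterations=0,
                           rng_seed=3, collapse_rule="none")
        result = multistart_search(m, None, EW, cfg)
        assert set(result.trees) >= {t1, t2}
        assert result.score == best

    def test_search_never_worse_than_start(self, rng):
        matrix, graph, _ = simulate_matrix(
            SimulationConfig(n_taxa=6, n_characters=12, rng_seed=2)
        )
        scorer = ParsimonyScorer(matrix, graph)
        start = random_topology(rng, matrix.taxon_labels)
        result = swap_to_local_optimum(start, scorer, "SPR")
        assert result.score <= scorer.total(start)
        scores = {scorer.total(t) for t in result.all_best}
        assert scores == {result.score}


class TestTreeCollection:
    def test_duplicate_add_counts_zero(self, clean_case):
        matrix, true = clean_case
        scorer = ParsimonyScorer(matrix)
        coll = TreeCollection()
        coll.add(true, "EW")
        _, added = update_tree_collection(coll, [true], scorer, "EW")
        assert added == 0

    def test_fresh_trees_counted(self, clean_case, rng):
        matrix, true = clean_case
        scorer = ParsimonyScorer(matrix)
        coll = TreeCollection()
        others = {random_topology(rng, matrix.taxon_labels) for _ in range(3)}
        _, added = update_tree_collection(coll, others | {true}, scorer, "x")
        assert added >= len(others | {true})  # plus any TBR discoveries

    def test_closure_terminates(self, clean_case):
        matrix, true = clean_case
        scorer = ParsimonyScorer(matrix)
        coll = TreeCollection()
        update_tree_collection(coll, [true], scorer, "EW")
        for _ in range(5):
            _, added = update_tree_collection(coll, [], scorer, "EW")
            if added == 0:
                break
        assert added == 0


class TestConsensus:
    def test_single_tree_is_itself(self, six_taxon_tree):
        assert strict_consensus([six_taxon_tree]) == six_taxon_tree

    def test_total_conflict_gives_star(self):
        a = PhyloTree.from_newick("((A,B),(C,D),(E,F));")
        b = PhyloTree.from_newick("((A,C),(B,E),(D,F));")
        cons = strict_consensus([a, b])
        assert cons.bipartitions == frozenset()

    def test_consensus_is_bipartition_intersection(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        trees = [random_topology(rng, taxa) for _ in range(5)]
        cons = strict_consensus(trees)
        assert cons.bipartitions == frozenset.intersection(
            *(t.bipartitions for t in trees)
        )

    def test_shared_subtree_is_retained(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        shared = frozenset({"t5", "t6", "t7"})
        trees = []
        while len(trees) < 6:
            t = random_topology(rng, taxa)
            if shared in t.bipartitions:
                trees.append(t)
        cons = strict_consensus(trees)
        assert shared in cons.bipartitions

    def test_mismatched_leaf_sets_rejected(self, six_taxon_tree, quartet):
        with pytest.raises(ValueError, match="leaf sets"):
            strict_consensus([six_taxon_tree, quartet])


class TestBootstrap:
    CFG = SearchConfig(replicates=1, hits_required=1, ratchet_iterations=0,
                       drift_iterations=0)

    def test_unanimous_split_reaches_100(self):
        taxa = list("ABCDEF")
        split = {"A", "B"}
        cols = [{t: int(t in split) for t in taxa} for _ in range(5)]
        chars = [Character(i, state_codes=(0, 1)) for i in range(5)]
        m = CharacterMatrix(taxa, chars, [[c[t] for c in cols] for t in taxa])
        support = bootstrap_support(m, None, EW, 20, self.CFG, seed=1)
        key = frozenset(taxa) - frozenset(split)
        sides = {frozenset(split), key}
        assert any(s in sides and v == 100.0 for s, v in support.items())

    def test_seeded_determinism(self, clean_case):
        matrix, _ = clean_case
        a = bootstrap_support(matrix, None, EW, 5, self.CFG, seed=9)
        b = bootstrap_support(matrix, None, EW, 5, self.CFG, seed=9)
        assert a == b

    def test_uninformative_matrix_resolves_nothing(self):
        taxa = list("ABCDE")
        chars = [Character(i, state_codes=(0, 1)) for i in range(4)]
        m = CharacterMatrix(taxa, chars, [[0] * 4 for _ in taxa])
        support = bootstrap_support(m, None, EW, 5, self.CFG, seed=2)
        assert support == {}
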