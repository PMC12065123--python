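"""Fitch/Sankoff scoring, homoplasy, implied weighting and sk."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from depclad import (
    Character,
    CharacterMatrix,
    EW,
    INAPPLICABLE,
    MISSING,
    ParsimonyScorer,
    PhyloTree,
    SimulationConfig,
    WeightingScheme,
    build_composite,
    compute_sk,
    enumerate_topologies,
    find_complexes,
    fitch_steps,
    iw_contribution,
    min_possible_cost,
    sankoff_cost,
    score_tree,
    simulate_matrix,
)

from conftest import (
    brute_force_min_cost,
    cell_state_indices,
    perfect_matrix,
    random_cells,
    random_topology,
    unit_cost_matrix,
)


class TestFitch:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ({"A": 0, "B": 0, "C": 1, "D": 1}, 1),
            ({"A": 0, "B": 1, "C": 0, "D": 1}, 2),
            ({"A": 0, "B": 0, "C": 1, "D": MISSING}, 1),
            ({"A": 0, "B": 0, "C": 1, "D": INAPPLICABLE}, 1),
            ({"A": frozenset({0, 1}), "B": 0, "C": 1, "D": 1}, 1),
        ],
    )
    def test_quartet_examples(self, quartet, cells, expected):
        ch = Character(0, state_codes=(0, 1))
        assert fitch_steps(quartet, ch, cells) == expected

    def test_missing_leaf_cell_raises(self, quartet):
        with pytest.raises(ValueError, match="D"):
            fitch_steps(quartet, Character(0), {"A": 0, "B": 0, "C": 1})

    def test_root_choice_is_irrelevant(self, rng):
        taxa = list("ABCDEF")
        ch = Character(0, state_codes=(0, 1, 2))
        for _ in range(5):
            cells = random_cells(rng, taxa, ch)
            t = random_topology(rng, taxa)
            rerooted = PhyloTree.from_newick(t.to_newick())
            assert fitch_steps(t, ch, cells) == fitch_steps(rerooted, ch, cells)


class TestOracleEquivalence:
    """Fitch and Sankoff agree with exhaustive enumeration on small trees."""

    @pytest.mark.parametrize("case", range(12))
    def test_fitch_equals_enumeration(self, rng, case):
        n_taxa = int(rng.integers(4, 7))
        taxa = [f"t{i}" for i in range(n_taxa)]
        n_states = int(rng.integers(2, 4))
        ch = Character(0, state_codes=tuple(range(n_states)))
        cells = random_cells(rng, taxa, ch)
        tree = random_topology(rng, taxa)
        allowed = {t: cell_state_indices(cells[t], ch) for t in taxa}
        oracle = brute_force_min_cost(tree, allowed, unit_cost_matrix(n_states))
        assert fitch_steps(tree, ch, cells) == oracle

    @pytest.mark.parametrize("seed", [3, 11, 27])
    def test_sankoff_equals_enumeration(self, seed):
        matrix, graph, _ = simulate_matrix(
            SimulationConfig(n_taxa=6, n_characters=12, rng_seed=seed)
        )
        rng = np.random.default_rng(seed)
        taxa = matrix.taxon_labels
        for members in find_complexes(graph, matrix.n_characters):
            if len(members) < 2:
                continue
            comp = build_composite(matrix, graph, members)
            tree = random_topology(rng, taxa)
            oracle = brute_force_min_cost(
                tree,
                {t: sorted(comp.taxon_state_sets[t]) for t in taxa},
                comp.cost_int,
            )
            assert sankoff_cost(tree, comp) == Fraction(int(oracle),
                                                        comp.cost_scale)

    def test_sankoff_constant_composite_is_zero(self, maddison_matrix):
        m, g = maddison_matrix
        m = m.copy()
        for row in m.cells:
            row[0], row[1] = 1, 0
        comp = build_composite(m, g, [0, 1])
        t = PhyloTree.from_newick("((A,B),(C,D));")
        assert sankoff_cost(t, comp) == 0


class TestMinPossible:
    def test_binary_both_states(self):
        ch = Character(0, state_codes=(0, 1))
        assert min_possible_cost(ch, {"a": 0, "b": 1}) == 1

    def test_three_observed_states(self):
        ch = Character(0, state_codes=(0, 1, 2))
        assert min_possible_cost(ch, {"a": 0, "b": 1, "c": 2, "d": MISSING}) == 2

    def test_maddison_steiner(self, maddison_matrix):
        m, g = maddison_matrix
        comp = build_composite(m, g, [0, 1])
        # observed: absent, present-red, present-blue -> 2 connection steps
        assert min_possible_cost(comp) == 2

    def test_min_never_exceeds_tree_cost(self, maddison_matrix, rng):
        m, g = maddison_matrix
        comp = build_composite(m, g, [0, 1])
        for t in enumerate_topologies(m.taxon_labels):
            assert min_possible_cost(comp) <= sankoff_cost(t, comp)


class TestImpliedWeighting:
    def test_zero_homoplasy_zero_fit(self):
        assert iw_contribution(0, 3) == 0.0

    def test_simple_ratio(self):
        assert iw_contribution(3, 3) == 0.5

    def test_composite_average_rule(self):
        # n=2 members, summed homoplasy 4 => hbar=2; 2*(2/(2+2)) = 1
        assert iw_contribution(4, 2, n=2) == 1.0

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            iw_contribution(1, 0)

    @pytest.mark.parametrize("h_max,N,k", [(14, 15, 1.0), (28, 15, 2.0)])
    def test_sk_formula(self, h_max, N, k):
        assert compute_sk(h_max, N) == k
        # the weight ratio really is N
        f0, fmax = 1.0, k / (h_max + k)
        assert f0 / fmax == pytest.approx(N)

    def test_sk_inversion_matches_reported_value(self):
        # k = h_max/(N-1) inverts to h_max = k*(N-1)
        assert compute_sk(76.211786, 15) == pytest.approx(5.443699)

    def test_sk_homoplasy_free_errors(self):
        with pytest.raises(ValueError, match="homoplasy-free"):
            compute_sk(0)


class TestScoreTree:
    def test_all_constant_scores_zero(self, six_taxon_tree):
        taxa = sorted(six_taxon_tree.leaf_set)
        chars = [Character(i, state_codes=(0, 1)) for i in range(4)]
        m = CharacterMatrix(taxa, chars, [[0] * 4 for _ in taxa])
        assert score_tree(six_taxon_tree, m).total_score == 0

    def test_ew_total_equals_per_character_brute_force(self, rng):
        taxa = list("ABCDEF")
        tree = random_topology(rng, taxa)
        chars = [Character(i, state_codes=(0, 1, 2)) for i in range(6)]
        cells_cols = [random_cells(rng, taxa, ch) for ch in chars]
        m = CharacterMatrix(
            taxa, chars,
            [[cells_cols[c][t] for c in range(6)] for t in taxa],
        )
        expected = sum(
            brute_force_min_cost(
                tree,
                {t: cell_state_indices(cells_cols[c][t], chars[c])
                 for t in taxa},
                unit_cost_matrix(3),
            )
            for c in range(6)
        )
        assert score_tree(tree, m).total_score == expected

    def test_iw_total_matches_unit_sum(self, rng):
        matrix, graph, led = simulate_matrix(
            SimulationConfig(n_taxa=7, n_characters=20, rng_seed=5)
        )
        scorer = ParsimonyScorer(matrix, graph, WeightingScheme("IW", k=4.0),
                                 use_composites=True)
        t = led.true_tree
        assert scorer.iw_total(t) == pytest.approx(
            sum(u.contribution for u in scorer.unit_scores(t)), abs=1e-9
        )

    def test_homoplasy_never_negative(self, rng):
        matrix, graph, _ = simulate_matrix(
            SimulationConfig(n_taxa=7, n_characters=20, rng_seed=13)
        )
        scorer = ParsimonyScorer(matrix, graph, use_composites=True)
        for _ in range(4):
            t = random_topology(rng, matrix.taxon_labels)
            assert all(u.homoplasy >= 0 for u in scorer.unit_scores(t))


class TestWeightingConsistency:
    def test_true_tree_dominates_under_all_schemes(self, rng):
        """A tree attaining every character's minimum beats any other tree
        under EW and under IW at any k (vector dominance)."""
        taxa = [f"t{i}" for i in range(7)]
        true = random_topology(rng, taxa)
        m = perfect_matrix(true, copies=2, extra_conflict=1)
        others = [random_topology(rng, taxa) for _ in range(8)]
        others = [t for t in others if t != true]
        for scheme in [EW] + [WeightingScheme("IW", k=k)
                              for k in (0.5, 3.0, 10.0, 100.0)]:
            scorer = ParsimonyScorer(m, scheme=scheme)
            s_true = scorer.total(true)
            for other in others:
                assert s_true < scorer.total(other)

    def test_iw_ranking_converges_to_ew(self, rng):
        """With unit weights, the IW ranking at very large k reproduces the
        EW ranking over all topologies."""
        taxa = list("ABCDEF")
        tree = random_topology(rng, taxa)
        m = perfect_matrix(tree, copies=1, extra_conflict=2)
        ew = ParsimonyScorer(m)
        iw = ParsimonyScorer(m, scheme=WeightingScheme("IW", k=1e6))
        topos = list(enumerate_topologies(taxa))
        ew_scores = [float(ew.total(t)) for t in topos]
        iw_scores = [iw.total(t) for t in topos]
        for i in range(len(topos)):
            for j in range(i + 1, len(topos)):
                if ew_scores[i] != ew_scores[j]:
                    assert (ew_scores[i] < ew_scores[j]) == (
                        iw_scores[i] < iw_scores[j]
                    )
                else:
                    assert iw_scores[i] == pytest.approx(iw_scores[j],
                                                         abs=1e-9)
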