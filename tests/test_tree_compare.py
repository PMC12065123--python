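"""Normalized Robinson-Foulds distances and congruence-based selection."""

import dendropy
import numpy as np
import pytest

from depclad import (
    PhyloTree,
    distance_matrix,
    internal_distance,
    nrf_distance,
    select_congruent_mpts,
)
from depclad.tree_search import strict_consensus

from conftest import random_topology


def _dendropy_rf(t1: PhyloTree, t2: PhyloTree) -> int:
    """Independent oracle: dendropy's unweighted RF on the same trees."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                          taxon_namespace=tns)
    b = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                          taxon_namespace=tns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b)


class TestNrf:
    def test_identical_trees(self, six_taxon_tree):
        assert nrf_distance(six_taxon_tree, six_taxon_tree) == 0.0

    def test_agrees_with_dendropy(self, rng):
        for n in (5, 7, 10):
            taxa = [f"t{i}" for i in range(n)]
            for _ in range(6):
                a = random_topology(rng, taxa)
                b = random_topology(rng, taxa)
                expected = _dendropy_rf(a, b) / (2 * (n - 3))
                assert nrf_distance(a, b) == pytest.approx(expected)

    def test_printed_value_convention_at_35_taxa(self, rng):
        """An RF of 8 over 35 taxa is 8/64 = 0.125, displayed as 0.13."""
        from depclad import nni_neighbors

        taxa = [f"s{i:02d}" for i in range(35)]
        a = random_topology(rng, taxa)
        b = a
        for _ in range(4):  # each step adds exactly 2 to the RF distance
            target = len(a.bipartitions ^ b.bipartitions) + 2
            b = next(
                nb for nb in nni_neighbors(b)
                if len(a.bipartitions ^ nb.bipartitions) == target
            )
        assert len(a.bipartitions ^ b.bipartitions) == 8
        assert nrf_distance(a, b) == pytest.approx(0.125)
        from depclad.tree_compare import display_round

        assert display_round(nrf_distance(a, b)) == 0.13

    def test_maximally_conflicting_trees(self):
        n = 35
        taxa = [f"s{i:02d}" for i in range(n)]

        def cater(order):
            nwk = f"({order[0]},{order[1]})"
            for t in order[2:]:
                nwk = f"({nwk},{t})"
            return PhyloTree.from_newick(nwk + ";")

        a = cater(taxa)
        b = cater(taxa[0::2] + taxa[1::2][::-1])
        assert a.bipartitions.isdisjoint(b.bipartitions)
        assert nrf_distance(a, b) == 1.0

    def test_leaf_set_mismatch(self, six_taxon_tree, quartet):
        with pytest.raises(ValueError, match="leaf sets"):
            nrf_distance(six_taxon_tree, quartet)

    def test_metric_axioms(self, rng):
        taxa = [f"t{i}" for i in range(9)]
        for _ in range(15):
            a, b, c = (random_topology(rng, taxa) for _ in range(3))
            dab, dba = nrf_distance(a, b), nrf_distance(b, a)
            assert dab == dba
            assert (dab == 0) == (a == b)
            assert nrf_distance(a, c) <= dab + nrf_distance(b, c) + 1e-12
            assert 0 <= dab <= 1


class TestDistanceMatrix:
    def test_identical_batch_all_zero(self, six_taxon_tree):
        dm = distance_matrix([("EW", [six_taxon_tree, six_taxon_tree])])
        assert dm.values.shape == (1, 1)  # deduplicated
        assert internal_distance([six_taxon_tree, six_taxon_tree]) == 0.0

    def test_two_batches_of_two(self, rng):
        taxa = [f"t{i}" for i in range(7)]
        trees = []
        while len(trees) < 4:
            t = random_topology(rng, taxa)
            if t not in trees:
                trees.append(t)
        dm = distance_matrix([("a", trees[:2]), ("b", trees[2:])])
        assert dm.values.shape == (4, 4)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_provenance_merged_for_shared_trees(self, six_taxon_tree):
        dm = distance_matrix([("EW", [six_taxon_tree]),
                              ("IWk3", [six_taxon_tree])])
        assert dm.labels == ["EW=IWk3"]

    def test_internal_distance_is_max_pairwise(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        batch = [random_topology(rng, taxa) for _ in range(4)]
        expected = max(
            nrf_distance(batch[i], batch[j])
            for i in range(4)
            for j in range(i + 1, 4)
        )
        assert internal_distance(batch) == expected

    def test_batch_order_equivariance(self, rng):
        taxa = [f"t{i}" for i in range(7)]
        a = [random_topology(rng, taxa) for _ in range(2)]
        b = [random_topology(rng, taxa) for _ in range(2)]
        d1 = distance_matrix([("a", a), ("b", b)])
        d2 = distance_matrix([("b", b), ("a", a)])
        assert sorted(map(tuple, d1.values)) == sorted(map(tuple, d2.values))


class TestCongruenceSelection:
    def test_identical_everywhere(self, six_taxon_tree):
        batches = {"sk": [six_taxon_tree], "EW": [six_taxon_tree]}
        sel = select_congruent_mpts(batches, ["sk"])
        assert sel.consensus == six_taxon_tree
        assert len(sel.selected) == 2

    def test_unique_nearest_per_batch(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        anchor = random_topology(rng, taxa)
        batches = {"sk": [anchor]}
        for name in ("EW", "IW"):
            pool = sorted(
                {random_topology(rng, taxa) for _ in range(12)} - {anchor},
                key=lambda t: nrf_distance(t, anchor),
            )
            # keep only a strictly-unique nearest tree
            chosen = [pool[0]] + [
                t for t in pool[1:]
                if nrf_distance(t, anchor) > nrf_distance(pool[0], anchor)
            ][:2]
            batches[name] = chosen
        sel = select_congruent_mpts(batches, ["sk"])
        assert len(sel.selected) == 1 + 2  # anchors + one per non-anchor batch

    def test_five_tree_combination(self, rng):
        """Two anchor MPTs plus the three equally closest trees of another
        batch combine into a five-tree strict consensus."""
        taxa = [f"t{i}" for i in range(9)]
        a1 = random_topology(rng, taxa)
        a2 = random_topology(rng, taxa)
        pool = list({random_topology(rng, taxa) for _ in range(40)} - {a1, a2})
        dist = [min(nrf_distance(t, a1), nrf_distance(t, a2)) for t in pool]
        order = np.argsort(dist, kind="stable")
        dmin = dist[order[0]]
        ties = [pool[i] for i in order if dist[i] == dmin][:3]
        assert len(ties) == 3, "fixture needs three equally close trees"
        farther = [pool[i] for i in order if dist[i] > dmin][:2]
        batches = {"skA": [a1], "skB": [a2], "xlEW": ties + farther}
        sel = select_congruent_mpts(batches, ["skA", "skB"])
        assert len(sel.selected) == 5
        assert sel.consensus == strict_consensus([a1, a2] + ties)

    def test_empty_batch_rejected(self, six_taxon_tree):
        with pytest.raises(ValueError, match="empty"):
            select_congruent_mpts({"a": [six_taxon_tree], "b": []}, ["a"])
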