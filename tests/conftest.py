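"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
import pytest

from depclad import (
    Character,
    CharacterMatrix,
    INAPPLICABLE,
    MISSING,
    PhyloTree,
    build_dependency_graph,
    enumerate_topologies,
)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_min_cost(tree, leaf_allowed, cost):
    """Exhaustive minimum over all internal-node state assignments.

    ``leaf_allowed`` maps leaf label -> iterable of allowed state indices;
    ``cost`` is a square matrix.  Completely independent of the package's
    Fitch/Sankoff dynamic programming.
    """
    cost = np.asarray(cost)
    adj = tree.adjacency
    labels = tree.leaf_ids
    internal = [v for v in adj if v not in labels]
    edges = tree.edges()
    n_states = cost.shape[0]
    best = None
    for assign in itertools.product(range(n_states), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        total = 0
        for u, v in edges:
            if u in labels:
                total += min(cost[amap[v], s] for s in leaf_allowed[labels[u]])
            elif v in labels:
                total += min(cost[amap[u], s] for s in leaf_allowed[labels[v]])
            else:
                total += cost[amap[u], amap[v]]
        if best is None or total < best:
            best = total
    return best


def cell_state_indices(cell, character):
    """Allowed state indices of a cell under missing-as-ambiguity scoring."""
    codes = list(character.state_codes)
    if cell is MISSING or cell is INAPPLICABLE:
        return list(range(len(codes)))
    if isinstance(cell, frozenset):
        return [codes.index(s) for s in sorted(cell)]
    return [codes.index(cell)]


def unit_cost_matrix(n_states):
    return np.ones((n_states, n_states), dtype=int) - np.eye(n_states, dtype=int)


def random_cells(rng, taxa, character, p_missing=0.15, p_poly=0.1):
    """Random cell column over a taxon list."""
    codes = character.state_codes
    out = {}
    for t in taxa:
        u = rng.random()
        if u < p_missing / 2:
            out[t] = MISSING
        elif u < p_missing:
            out[t] = INAPPLICABLE
        elif u < p_missing + p_poly and len(codes) >= 2:
            pair = rng.choice(len(codes), size=2, replace=False)
            out[t] = frozenset(codes[i] for i in pair)
        else:
            out[t] = int(codes[rng.integers(len(codes))])
    return out


def random_topology(rng, taxa):
    """One random unrooted binary topology (random sequential insertion)."""
    taxa = list(taxa)
    adj = {0: [1], 1: [0, 2, 3], 2: [1], 3: [1]}
    labels = {0: taxa[0], 2: taxa[1], 3: taxa[2]}
    counter = 4
    for taxon in taxa[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        x, y = edges[rng.integers(len(edges))]
        mid, leaf = counter, counter + 1
        adj[x] = [mid if t == y else t for t in adj[x]]
        adj[y] = [mid if t == x else t for t in adj[y]]
        adj[mid] = [x, y, leaf]
        adj[leaf] = [mid]
        labels[leaf] = taxon
        counter += 2
    return PhyloTree(adj, labels)


def perfect_matrix(tree, copies=1, extra_conflict=0):
    """Matrix whose binary characters are exactly the tree's bipartitions
    (repeated ``copies`` times), plus optional characters that conflict by
    grouping two non-adjacent leaves."""
    taxa = sorted(tree.leaf_set)
    columns = []
    for bip in sorted(tree.bipartitions, key=sorted):
        for _ in range(copies):
            columns.append({t: int(t in bip) for t in taxa})
    for i in range(extra_conflict):
        pair = (taxa[0], taxa[-1 - i])
        columns.append({t: int(t in pair) for t in taxa})
    chars = [Character(i, state_codes=(0, 1)) for i in range(len(columns))]
    cells = [[col[t] for col in columns] for t in taxa]
    return CharacterMatrix(taxa, chars, cells)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def quartet():
    return PhyloTree.from_newick("((A,B),(C,D));")


@pytest.fixture
def six_taxon_tree():
    return PhyloTree.from_newick("(((A,B),C),(D,(E,F)));")


@pytest.fixture
def maddison_matrix():
    chars = [
        Character(0, "Tail: (0) absent, (1) present", "neomorphic", (0, 1)),
        Character(1, "[1.1>this] Tail colour: (0) red, (1) blue"),
    ]
    taxa = ["A", "B", "C", "D"]
    cells = [[1, 0], [1, 1], [0, INAPPLICABLE], [0, INAPPLICABLE]]
    m = CharacterMatrix(taxa, chars, cells)
    return m, build_dependency_graph(m)
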