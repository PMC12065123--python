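"""Synthetic character matrices with known evolutionary truth.

The generator evolves discrete characters along a known tree under a
fixed-number-of-changes model (change counts drawn per character, changes
placed on random edges), so the truth ledger holds exact integers for every
oracle.  It reproduces the structural features the analyses assume:

* hierarchical dependency complexes — a binary controller whose absence makes
  its dependents inapplicable, arranged as stars or chains;
* serial-homologue blocks over ordered positions, optionally constrained to
  transform as contiguous streaks;
* uniformly injected missing data (default ~12.85% of cells, the proportion
  typical of a curated morphological matrix of this size, with an optional
  per-taxon skew);
* the classic tail/colour configuration in which scoring an inapplicable
  cell as missing data biases the choice between two equally costly
  two-origin topologies.

Dependent characters carry the in-statement dependency annotation, so the
ordinary parsing path (:func:`depclad.dependency_model.build_dependency_graph`)
recovers the generating structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .dependency_model import (
    DependencyGraph,
    SerialBlock,
    build_dependency_graph,
)
from .matrix_io import (
    INAPPLICABLE,
    MISSING,
    CellValue,
    Character,
    CharacterMatrix,
)
from .parsimony_scoring import _rooted_order
from .trees import PhyloTree

NA = INAPPLICABLE


@dataclass
class SimulationConfig:
    n_taxa: int = 10
    n_characters: int = 40
    dependency_fraction: float = 0.67
    complex_size_range: Tuple[int, int] = (2, 5)
    serial_blocks: Sequence[Tuple[int, bool]] = ()  # (length, streak flag)
    missing_fraction: float = 0.1285
    state_change_rate: float = 1.0
    rng_seed: int = 0
    true_tree: Optional[PhyloTree] = None
    base_weight: Fraction = Fraction(1)
    taxon_missing: Optional[Mapping[str, float]] = None  # per-taxon skew

    def __post_init__(self) -> None:
        if not (0 <= self.dependency_fraction <= 1 and 0 <= self.missing_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.n_taxa < 4 or self.n_characters < 1:
            raise ValueError("need >= 4 taxa and >= 1 character")
        lo, hi = self.complex_size_range
        if not (2 <= lo <= hi):
            raise ValueError("complex sizes must be >= 2 and ordered")
        total_serial = sum(length for length, _ in self.serial_blocks)
        if total_serial + (hi if self.dependency_fraction > 0 else 0) > self.n_characters:
            raise ValueError("complex/serial sizes exceed the character count")


@dataclass
class TruthLedger:
    """Exact bookkeeping of the generating process, for oracle tests."""

    true_tree: PhyloTree
    node_values: List[Dict[int, object]]  # per character: node id -> state/NA
    change_counts: List[int]  # changes placed (gains excluded)
    gain_counts: List[int]  # free instantiations at applicability gains
    complexes: List[Set[int]]
    serial_members: Set[int]
    participating: Set[int]

    def upper_bound_steps(self, char_index: int) -> int:
        """True changes + gain instantiations: an upper bound on any
        parsimony step count for this character on the true tree."""
        return self.change_counts[char_index] + self.gain_counts[char_index]


def _random_tree(taxa: Sequence[str], rng: np.random.Generator) -> PhyloTree:
    adj: Dict[int, List[int]] = {0: [1], 1: [0, 2, 3], 2: [1], 3: [1]}
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


def _pick_changes(
    rng: np.random.Generator, eligible: Sequence, rate: float
) -> List:
    if not len(eligible):
        return []
    c = min(int(rng.poisson(rate)), len(eligible))
    if c == 0:
        return []
    idx = rng.choice(len(eligible), size=c, replace=False)
    return [eligible[i] for i in np.atleast_1d(idx)]


def _evolve_plain(
    rng: np.random.Generator,
    order: Sequence[Tuple[int, int]],
    codes: Sequence[int],
    rate: float,
) -> Tuple[Dict[int, int], int]:
    edges = [(v, p) for v, p in order if p >= 0]
    changes = set(map(tuple, _pick_changes(rng, edges, rate)))
    values: Dict[int, int] = {}
    for v, parent in order:
        if parent < 0:
            values[v] = int(rng.choice(codes))
        elif (v, parent) in changes:
            alternatives = [s for s in codes if s != values[parent]]
            values[v] = int(rng.choice(alternatives))
        else:
            values[v] = values[parent]
    return values, len(changes)


def _evolve_dependent(
    rng: np.random.Generator,
    order: Sequence[Tuple[int, int]],
    codes: Sequence[int],
    rate: float,
    applicable: Set[int],
) -> Tuple[Dict[int, object], int, int]:
    eligible = [
        (v, p) for v, p in order if p >= 0 and v in applicable and p in applicable
    ]
    changes = set(map(tuple, _pick_changes(rng, eligible, rate)))
    values: Dict[int, object] = {}
    gains = 0
    for v, parent in order:
        if v not in applicable:
            values[v] = NA
        elif parent < 0 or values[parent] is NA:
            values[v] = int(rng.choice(codes))
            if parent >= 0:
                gains += 1
        elif (v, parent) in changes:
            alternatives = [s for s in codes if s != values[parent]]
            values[v] = int(rng.choice(alternatives))
        else:
            values[v] = values[parent]
    return values, len(changes), gains


def _streak_neighbours(state: Optional[Tuple[int, int]], length: int):
    """Adjacent streaks: grow/shrink one end; empty <-> single position."""
    if state is None:
        return [(i, i) for i in range(length)]
    a, b = state
    out = []
    if a > 0:
        out.append((a - 1, b))
    if b < length - 1:
        out.append((a, b + 1))
    if a < b:
        out.append((a + 1, b))
        out.append((a, b - 1))
    if a == b:
        out.append(None)
    return out


def _evolve_streak(
    rng: np.random.Generator,
    order: Sequence[Tuple[int, int]],
    length: int,
    rate: float,
) -> Tuple[Dict[int, Optional[Tuple[int, int]]], int]:
    edges = [(v, p) for v, p in order if p >= 0]
    changes = set(map(tuple, _pick_changes(rng, edges, rate)))
    values: Dict[int, Optional[Tuple[int, int]]] = {}
    for v, parent in order:
        if parent < 0:
            if rng.random() < 0.25:
                values[v] = None
            else:
                a = int(rng.integers(length))
                b = int(rng.integers(a, length))
                values[v] = (a, b)
        elif (v, parent) in changes:
            nbs = _streak_neighbours(values[parent], length)
            values[v] = nbs[rng.integers(len(nbs))]
        else:
            values[v] = values[parent]
    return values, len(changes)


def simulate_matrix(
    config: SimulationConfig,
) -> Tuple[CharacterMatrix, DependencyGraph, TruthLedger]:
    """Generate a dependency-consistent matrix on a known tree.

    Dependent characters evolve only inside tree regions where all their
    controllers are present, so the raw matrix always passes dependency
    validation; missing data is injected afterwards and can never create a
    violation.
    """
    rng = np.random.default_rng(config.rng_seed)
    taxa = [f"t{i + 1:02d}" for i in range(config.n_taxa)]
    tree = config.true_tree or _random_tree(taxa, rng)
    if set(tree.leaf_set) != set(taxa) and config.true_tree is not None:
        taxa = sorted(tree.leaf_set)
    order = _rooted_order(tree)
    leaf_of = tree.leaf_ids

    n = config.n_characters
    statements = [""] * n
    char_codes: List[Tuple[int, ...]] = [(0, 1)] * n
    serial_defs: List[SerialBlock] = []
    node_values: List[Dict[int, object]] = [dict() for _ in range(n)]
    change_counts = [0] * n
    gain_counts = [0] * n
    complexes: List[Set[int]] = []
    serial_members: Set[int] = set()

    cursor = 0
    # serial blocks occupy the leading characters
    for length, streak in config.serial_blocks:
        members = tuple(range(cursor, cursor + length))
        serial_defs.append(SerialBlock(members, streak_constrained=streak))
        serial_members |= set(members)
        if streak:
            streaks, c = _evolve_streak(rng, order, length, config.state_change_rate)
            for j, m in enumerate(members):
                node_values[m] = {
                    v: int(s is not None and s[0] <= j <= s[1])
                    for v, s in streaks.items()
                }
            change_counts[members[0]] = c  # block-level count on its first member
        else:
            for m in members:
                node_values[m], change_counts[m] = _evolve_plain(
                    rng, order, (0, 1), config.state_change_rate
                )
        for m in members:
            statements[m] = f"Serial position {m - cursor + 1}: (0) absent, (1) present"
        cursor += length

    # dependency complexes until the participation target is met
    target = round(config.dependency_fraction * n)
    lo, hi = config.complex_size_range
    participating = set(serial_members)
    while len(participating) < target and cursor + lo <= n:
        size = int(rng.integers(lo, hi + 1))
        size = min(size, n - cursor)
        members = list(range(cursor, cursor + size))
        controller = members[0]
        chain = size >= 3 and rng.random() < 0.5
        node_values[controller], change_counts[controller] = _evolve_plain(
            rng, order, (0, 1), config.state_change_rate
        )
        statements[controller] = (
            f"Structure {controller + 1}: (0) absent, (1) present"
        )
        applicable_of: Dict[int, Set[int]] = {
            controller: {v for v, s in node_values[controller].items() if s == 1}
        }
        for depth, m in enumerate(members[1:], start=1):
            ctrl = members[depth - 1] if chain else controller
            applicable = applicable_of[ctrl] & {
                v for v, s in node_values[ctrl].items() if s == 1
            }
            is_tip = (not chain and depth == size - 1) or (chain and depth == size - 1)
            codes = (
                tuple(range(int(rng.integers(2, 5))))
                if is_tip and rng.random() < 0.4
                else (0, 1)
            )
            char_codes[m] = codes
            node_values[m], change_counts[m], gain_counts[m] = _evolve_dependent(
                rng, order, codes, config.state_change_rate, applicable
            )
            statements[m] = (
                f"[{ctrl + 1}.1>this] Condition of structure {ctrl + 1},"
                f" aspect {depth}: "
                + ", ".join(f"({s}) state{s}" for s in codes)
            )
            applicable_of[m] = {v for v, s in node_values[m].items() if s != NA}
        complexes.append(set(members))
        participating |= set(members)
        cursor += size

    # remaining characters are independent
    for m in range(cursor, n):
        u = rng.random()
        n_states = 2 if u < 0.6 else (3 if u < 0.85 else 4)
        codes = tuple(range(n_states))
        char_codes[m] = codes
        node_values[m], change_counts[m] = _evolve_plain(
            rng, order, codes, config.state_change_rate
        )
        statements[m] = f"Independent character {m + 1}: " + ", ".join(
            f"({s}) state{s}" for s in codes
        )

    characters = [
        Character(
            index=m,
            statement=statements[m],
            char_type="neomorphic"
            if char_codes[m] == (0, 1) and "absent" in statements[m]
            else "transformational",
            state_codes=char_codes[m],
            weight=config.base_weight,
        )
        for m in range(n)
    ]
    cells: List[List[CellValue]] = []
    for leaf_id, label in sorted(leaf_of.items(), key=lambda kv: kv[1]):
        row: List[CellValue] = []
        for m in range(n):
            val = node_values[m][leaf_id]
            row.append(INAPPLICABLE if val is NA else int(val))
        cells.append(row)
    taxon_order = sorted(leaf_of.values())
    matrix = CharacterMatrix(taxon_order, characters, cells)

    # inject missing data (uniform, with optional per-taxon skew)
    for i, taxon in enumerate(matrix.taxon_labels):
        frac = config.missing_fraction
        if config.taxon_missing and taxon in config.taxon_missing:
            frac = config.taxon_missing[taxon]
        for c in range(n):
            if frac and rng.random() < frac:
                matrix.cells[i][c] = MISSING

    graph = build_dependency_graph(matrix, serial_blocks=serial_defs)
    ledger = TruthLedger(
        true_tree=tree,
        node_values=node_values,
        change_counts=change_counts,
        gain_counts=gain_counts,
        complexes=complexes,
        serial_members=serial_members,
        participating=participating,
    )
    return matrix, graph, ledger


def true_composite_cost(ledger: TruthLedger, composite) -> Fraction:
    """Cost of the true (generating) assignment of a composite on the true
    tree: an upper bound on the Sankoff minimum."""
    order = _rooted_order(ledger.true_tree)
    index = {tup: i for i, tup in enumerate(composite.states)}
    total = 0
    for v, parent in order:
        if parent < 0:
            continue
        tv = tuple(ledger.node_values[m][v] for m in composite.members)
        tp = tuple(ledger.node_values[m][parent] for m in composite.members)
        total += int(composite.cost_int[index[tp], index[tv]])
    return Fraction(total, composite.cost_scale)


# ---------------------------------------------------------------------------
# The tail/colour fixture
# ---------------------------------------------------------------------------

def maddison_fixture() -> Tuple[CharacterMatrix, DependencyGraph, Tuple[PhyloTree, PhyloTree]]:
    """Eight taxa, a neomorphic "tail" controller and a dependent "colour".

    t1 and t2 carry red tails, t5 and t6 blue tails; t3, t4, t7 and t8 are
    tailless.  Both returned topologies imply exactly two independent tail
    origins (the tail character alone needs two steps on either), and the
    composite treatment scores them identically.  Scoring the inapplicable
    colour cells as missing data instead reconstructs tail colours for
    tailless ancestors, and that phantom information separates the two
    topologies — the classic artifact of conflating inapplicable with
    unknown.  The pair was located by exhaustive enumeration of all 10395
    eight-taxon topologies.
    """
    chars = [
        Character(0, "Tail: (0) absent, (1) present", "neomorphic", (0, 1)),
        Character(1, "[1.1>this] Tail colour: (0) red, (1) blue",
                  "transformational", (0, 1)),
    ]
    taxa = ["t1", "t2", "t3", "t4", "t5", "t6", "t7", "t8"]
    tail = {"t1": 1, "t2": 1, "t3": 0, "t4": 0, "t5": 1, "t6": 1, "t7": 0, "t8": 0}
    colour = {"t1": 0, "t2": 0, "t5": 1, "t6": 1}
    cells = [
        [tail[t], colour.get(t, INAPPLICABLE)] for t in taxa
    ]
    matrix = CharacterMatrix(taxa, chars, cells)
    graph = build_dependency_graph(matrix)
    topo_a = PhyloTree.from_newick("(((((t2,t3),t8),t7),t4),(t5,t6),t1);")
    topo_b = PhyloTree.from_newick("((((((t2,t3),t8),t7),t4),t5),t1,t6);")
    return matrix, graph, (topo_a, topo_b)


# ---------------------------------------------------------------------------
# The uniramous-pleopod fixture
# ---------------------------------------------------------------------------

def uniramy_fixture() -> Dict[str, Tuple[CharacterMatrix, DependencyGraph]]:
    """A matrix with an endopod complex and an exopod complex, scored in three
    variants for one uniramous taxon whose single ramus is of ambiguous
    identity: ``exopod-present`` (the adopted reading), ``endopod-present``,
    and ``both-missing``.  The both-missing variant admits optimizations in
    which the taxon has both rami present (or both absent) — configurations
    that are anatomically impossible for a uniramous appendage.
    """
    chars = [
        Character(0, "Pleopod endopods: (0) absent, (1) present",
                  "neomorphic", (0, 1)),
        Character(1, "[1.1>this] Endopod segmentation: (0) unsegmented,"
                     " (1) segmented"),
        Character(2, "[1.1>this] Endopod setation: (0) sparse, (1) dense"),
        Character(3, "Pleopod exopods: (0) absent, (1) present",
                  "neomorphic", (0, 1)),
        Character(4, "[4.1>this] Exopod segmentation: (0) unsegmented,"
                     " (1) multi-annulated"),
        Character(5, "[4.1>this] Exopod setation: (0) sparse, (1) dense"),
        Character(6, "[4.1>this] Exopod shape: (0) lobate, (1) flagelliform"),
        Character(7, "[4.1>this] Exopod size: (0) short, (1) elongate"),
    ]
    taxa = ["out", "bi1", "bi2", "bi3", "bi4", "uni"]
    biramous = {
        "out": [1, 0, 0, 1, 0, 0, 0, 0],
        "bi1": [1, 1, 1, 1, 1, 1, 1, 1],
        "bi2": [1, 1, 1, 1, 1, 1, 1, 1],
        "bi3": [1, 1, 0, 1, 1, 0, 1, 1],
        "bi4": [1, 0, 1, 1, 0, 1, 0, 1],
    }
    uni_rows = {
        "exopod-present": [0, INAPPLICABLE, INAPPLICABLE, 1, 1, 1, 1, 1],
        "endopod-present": [1, 1, 1, 0, INAPPLICABLE, INAPPLICABLE,
                            INAPPLICABLE, INAPPLICABLE],
        "both-missing": [MISSING] * 8,
    }
    out = {}
    for name, uni in uni_rows.items():
        cells = [list(biramous[t]) if t != "uni" else list(uni) for t in taxa]
        matrix = CharacterMatrix(list(taxa), list(chars), cells)
        out[name] = (matrix, build_dependency_graph(matrix))
    return out
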