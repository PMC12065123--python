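"""Flattening dependency complexes into composite characters.

Each connected complex of the dependency graph (links plus serial blocks)
becomes a single character whose states are the dependency-consistent tuples
of constituent states and whose transformation costs are given by a step
(cost) matrix.  The cost rule never charges a dependent for appearing or
vanishing with its controller: the controller's own change carries that cost,
which is exactly what makes independently gained structures neutral with
respect to their dependent properties (the tail-colour problem).  Serial
blocks charge m concurrent homomorph changes as w*(1 + (m-1)*discount)
instead of m*w.  A metric closure (all-pairs shortest path) is applied so the
matrix is a valid Sankoff step matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import lcm
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .dependency_model import DependencyGraph, SerialBlock
from .matrix_io import INAPPLICABLE, MISSING, CharacterMatrix

#: entry used inside state tuples for an inapplicable constituent
NA = INAPPLICABLE

StateTuple = Tuple[object, ...]


class StateSpaceError(ValueError):
    """The composite state space exceeds the configured cap; split the complex."""


@dataclass
class CompositeCharacter:
    """A dependency complex recoded as one Sankoff character."""

    members: Tuple[int, ...]  # original character indices, ascending
    states: Tuple[StateTuple, ...]
    cost: np.ndarray  # float view of the step matrix (after metric closure)
    cost_int: np.ndarray  # exact integer costs == cost * cost_scale
    cost_scale: int
    taxon_state_sets: Dict[str, FrozenSet[int]]  # indices into `states`
    weight_scale: Fraction  # common member weight (1 when members differ)

    @property
    def n_members(self) -> int:
        return len(self.members)

    def cost_between(self, i: int, j: int) -> Fraction:
        return Fraction(int(self.cost_int[i, j]), self.cost_scale)

    def to_report(self) -> dict:
        return {
            "members": [m + 1 for m in self.members],
            "states": [
                ["-" if s is NA else s for s in tup] for tup in self.states
            ],
            "costs": [[float(c) for c in row] for row in self.cost],
        }


def find_complexes(graph: DependencyGraph, n_characters: int) -> List[FrozenSet[int]]:
    """Partition all characters into connected complexes (>=2 members, linked
    by dependencies or a shared serial block) and singletons."""
    g = nx.Graph()
    g.add_nodes_from(range(n_characters))
    for l in graph.links:
        g.add_edge(l.controller, l.dependent)
    for b in graph.serial_blocks:
        for a, z in zip(b.members, b.members[1:]):
            g.add_edge(a, z)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    return sorted(comps, key=min)


def _member_order(members: Sequence[int], graph: DependencyGraph) -> List[int]:
    """Members sorted so that controllers precede their dependents."""
    dg = nx.DiGraph()
    dg.add_nodes_from(members)
    mset = set(members)
    for l in graph.links:
        if l.controller in mset and l.dependent in mset:
            dg.add_edge(l.controller, l.dependent)
    return list(nx.lexicographical_topological_sort(dg))


def _streak_ok(block: SerialBlock, entry_of: Mapping[int, object]) -> bool:
    present = [
        i
        for i, m in enumerate(block.members)
        if entry_of.get(m) not in (0, NA, None)
    ]
    return all(b - a == 1 for a, b in zip(present, present[1:]))


def enumerate_states(
    complex_members: Iterable[int],
    matrix: CharacterMatrix,
    graph: DependencyGraph,
    cap: int = 4096,
) -> List[StateTuple]:
    """All dependency-consistent tuples over the complex, in lexicographic
    order (inapplicable sorts before every state code)."""
    members = sorted(complex_members)
    order = _member_order(members, graph)
    pos = {m: i for i, m in enumerate(members)}
    blocks = [
        b
        for b in graph.serial_blocks
        if b.streak_constrained and set(b.members) <= set(members)
    ]
    results: List[StateTuple] = []

    def extend(assign: Dict[int, object], k: int) -> None:
        if len(results) > cap:
            raise StateSpaceError(
                f"composite state space for characters {[m + 1 for m in members]}"
                f" exceeds cap {cap}; split the complex"
            )
        if k == len(order):
            if all(_streak_ok(b, assign) for b in blocks):
                tup = tuple(assign[m] for m in members)
                results.append(tup)
            return
        m = order[k]
        full = graph.full_controllers_of(m)
        blocked = False
        for l in full:
            if l.controller in assign:
                val = assign[l.controller]
                if val is NA or val not in l.enabling_states:
                    blocked = True
                    break
        if blocked:
            assign[m] = NA
            extend(assign, k + 1)
            del assign[m]
            return
        allowed: Set[int] = set(matrix.characters[m].state_codes)
        for l in graph.controllers_of(m):
            if l.dependent_states is None or l.controller not in assign:
                continue
            val = assign[l.controller]
            if val is NA or val not in l.enabling_states:
                allowed -= l.dependent_states
        if not allowed:
            assign[m] = NA
            extend(assign, k + 1)
            del assign[m]
            return
        for s in sorted(allowed):
            assign[m] = s
            extend(assign, k + 1)
            del assign[m]

    extend({}, 0)

    def key(tup: StateTuple) -> tuple:
        return tuple(-1 if v is NA else v for v in tup)

    return sorted(results, key=key)


def _rule_cost(
    u: StateTuple,
    v: StateTuple,
    members: Sequence[int],
    weights: Mapping[int, Fraction],
    blocks: Sequence[SerialBlock],
) -> Fraction:
    in_block = {m for b in blocks for m in b.members}
    pos = {m: i for i, m in enumerate(members)}
    total = Fraction(0)
    for b in blocks:
        changed = [
            m
            for m in b.members
            if m in pos
            and u[pos[m]] is not NA
            and v[pos[m]] is not NA
            and u[pos[m]] != v[pos[m]]
        ]
        if changed:
            w = weights[changed[0]]
            total += w * (1 + (len(changed) - 1) * b.concurrency_discount)
    for i, m in enumerate(members):
        if m in in_block:
            continue
        if u[i] is not NA and v[i] is not NA and u[i] != v[i]:
            total += weights[m]
    return total


def build_cost_matrix(
    states: Sequence[StateTuple],
    members: Sequence[int],
    weights: Mapping[int, Fraction],
    serial_blocks: Sequence[SerialBlock] = (),
    allow_zero_weight: bool = False,
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Step costs between composite states: rule-based direct costs followed
    by a metric closure.  Returns (float matrix, exact integer matrix, scale).
    """
    for m in members:
        w = weights[m]
        if w < 0 or (w == 0 and not allow_zero_weight):
            raise ValueError(f"character {m + 1} has non-positive weight {w}")
    blocks = [b for b in serial_blocks if set(b.members) & set(members)]
    n = len(states)
    frac = [[Fraction(0)] * n for _ in range(n)]
    denoms = {1}
    for i in range(n):
        for j in range(i + 1, n):
            c = _rule_cost(states[i], states[j], list(members), weights, blocks)
            frac[i][j] = frac[j][i] = c
            denoms.add(c.denominator)
    scale = lcm(*denoms)
    ci = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(n):
            ci[i, j] = int(frac[i][j] * scale)
    # metric closure: Floyd-Warshall so indirect routes beat any overcharge
    for k in range(n):
        np.minimum(ci, ci[:, k][:, None] + ci[k, :][None, :], out=ci)
    return ci.astype(float) / scale, ci, scale


def _compatible_states(
    cell, member_pos: int, states: Sequence[StateTuple]
) -> Set[int]:
    out = set()
    for idx, tup in enumerate(states):
        e = tup[member_pos]
        if cell is MISSING:
            out.add(idx)
        elif cell is INAPPLICABLE:
            if e is NA:
                out.add(idx)
        elif isinstance(cell, frozenset):
            if e is not NA and e in cell:
                out.add(idx)
        else:
            if e == cell:
                out.add(idx)
    return out


def build_composite(
    matrix: CharacterMatrix,
    graph: DependencyGraph,
    complex_members: Iterable[int],
    cap: int = 4096,
    allow_zero_weight: bool = False,
) -> CompositeCharacter:
    """Build the composite character for one complex: enumerate consistent
    tuples, derive the step matrix, and map every taxon to its compatible
    tuple set (missing and polymorphic cells expand the set)."""
    members = tuple(sorted(complex_members))
    states = tuple(enumerate_states(members, matrix, graph, cap=cap))
    weights = {m: matrix.characters[m].weight for m in members}
    cost, cost_int, scale = build_cost_matrix(
        states, members, weights,
        serial_blocks=graph.serial_blocks,
        allow_zero_weight=allow_zero_weight,
    )
    taxon_state_sets: Dict[str, FrozenSet[int]] = {}
    for t, taxon in enumerate(matrix.taxon_labels):
        allowed: Optional[Set[int]] = None
        for p, m in enumerate(members):
            comp = _compatible_states(matrix.cells[t][m], p, states)
            allowed = comp if allowed is None else allowed & comp
        if not allowed:
            raise ValueError(
                f"taxon {taxon!r} has no dependency-consistent composite state"
                f" for characters {[m + 1 for m in members]}"
            )
        taxon_state_sets[taxon] = frozenset(allowed)
    wset = {weights[m] for m in members}
    return CompositeCharacter(
        members=members,
        states=states,
        cost=cost,
        cost_int=cost_int,
        cost_scale=scale,
        taxon_state_sets=taxon_state_sets,
        weight_scale=wset.pop() if len(wset) == 1 else Fraction(1),
    )
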