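"""Tree scoring: Fitch steps, generalized (Sankoff) parsimony for composite
characters, homoplasy, implied-weighting fits and the automatic concavity
constant sk.

Equal weighting (EW) minimizes total weighted steps.  Implied weighting (IW)
minimizes the summed fit cost h/(h+k) per character, where h is homoplasy
(steps above the character's tree-independent minimum) and k the concavity
constant.  A composite character spanning n constituents contributes
n * (hbar/(hbar+k)) with hbar = h/n, i.e. the fit of its averaged homoplasy
counted once per constituent.  The automatic sk makes a homoplasy-free
character outweigh the most homoplastic one by exactly the ratio N:
f(0)/f(h_max) = (k+h_max)/k = N, hence k = h_max/(N-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .composite_builder import (
    CompositeCharacter,
    build_composite,
    find_complexes,
)
from .dependency_model import DependencyGraph
from .matrix_io import (
    INAPPLICABLE,
    MISSING,
    CellValue,
    Character,
    CharacterMatrix,
)
from .trees import PhyloTree

_INF = np.int64(10**15)


@dataclass(frozen=True)
class WeightingScheme:
    """EW or IW with concavity k; ratio_N drives the automatic sk."""

    mode: str = "EW"
    k: Optional[float] = None
    ratio_N: float = 15.0

    def __post_init__(self) -> None:
        if self.mode not in ("EW", "IW"):
            raise ValueError("mode must be 'EW' or 'IW'")
        if self.mode == "IW" and (self.k is None or self.k <= 0):
            raise ValueError("IW requires k > 0")
        if self.ratio_N <= 1:
            raise ValueError("ratio_N must exceed 1")

    @property
    def label(self) -> str:
        if self.mode == "EW":
            return "EW"
        return f"IWk{self.k:g}"


EW = WeightingScheme("EW")


# ---------------------------------------------------------------------------
# Traversals and DP kernels
# ---------------------------------------------------------------------------

def _rooted_order(tree: PhyloTree) -> List[Tuple[int, int]]:
    """Preorder list of (node, parent) rooted at the attachment node of the
    alphabetically smallest leaf (parent == -1 for the root)."""
    adj = tree.adjacency
    labels = tree.leaf_ids
    ref = min(labels.values())
    ref_id = next(v for v, lab in labels.items() if lab == ref)
    root = adj[ref_id][0]
    order: List[Tuple[int, int]] = []
    stack = [(root, -1)]
    while stack:
        v, parent = stack.pop()
        order.append((v, parent))
        for u in adj[v]:
            if u != parent:
                stack.append((u, v))
    return order


def _fitch_masks(
    adj: Mapping[int, Tuple[int, ...]],
    labels: Mapping[int, str],
    order: Sequence[Tuple[int, int]],
    masks: Mapping[str, int],
) -> int:
    steps = 0
    down: Dict[int, int] = {}
    for v, parent in reversed(order):
        if v in labels:
            down[v] = masks[labels[v]]
            continue
        acc = -1
        for u in adj[v]:
            if u == parent:
                continue
            m = down[u]
            if acc == -1:
                acc = m
            else:
                inter = acc & m
                if inter:
                    acc = inter
                else:
                    acc |= m
                    steps += 1
        down[v] = acc
    return steps


_BIG = np.int64(10**12)


def _build_batch(
    cost_mats: Sequence[np.ndarray],
    leaf_sets: Sequence[Mapping[str, FrozenSet[int]]],
    taxa: Sequence[str],
) -> Optional[dict]:
    """Pad heterogeneous state spaces so all units run in one vectorized DP."""
    if not cost_mats:
        return None
    u_count = len(cost_mats)
    s_max = max(c.shape[0] for c in cost_mats)
    cost = np.full((u_count, s_max, s_max), _BIG, dtype=np.int64)
    for u, c in enumerate(cost_mats):
        s = c.shape[0]
        cost[u, :s, :s] = c
    leaf: Dict[str, np.ndarray] = {}
    for t in taxa:
        m = np.full((u_count, s_max), _BIG, dtype=np.int64)
        for u, sets in enumerate(leaf_sets):
            allowed = sets[t]
            if not allowed:
                raise ValueError(f"empty state set for taxon {t!r}")
            m[u, list(allowed)] = 0
        leaf[t] = m
    return {"cost": cost, "leaf": leaf}


def _batched_sankoff(
    adj: Mapping[int, Tuple[int, ...]],
    labels: Mapping[int, str],
    order: Sequence[Tuple[int, int]],
    batch: dict,
) -> np.ndarray:
    """Simultaneous Sankoff DP for every unit in the batch; returns the
    integer minimum per unit."""
    cost = batch["cost"]
    leaf = batch["leaf"]
    g: Dict[int, np.ndarray] = {}
    for v, parent in reversed(order):
        if v in labels:
            g[v] = leaf[labels[v]]
            continue
        acc = None
        for u in adj[v]:
            if u == parent:
                continue
            contrib = np.min(cost + g[u][:, None, :], axis=2)
            acc = contrib if acc is None else acc + contrib
        g[v] = acc
    return g[order[0][0]].min(axis=1)


def _sankoff_masks(
    adj: Mapping[int, Tuple[int, ...]],
    labels: Mapping[int, str],
    order: Sequence[Tuple[int, int]],
    cost: np.ndarray,
    taxon_state_sets: Mapping[str, FrozenSet[int]],
) -> int:
    n_states = cost.shape[0]
    g: Dict[int, np.ndarray] = {}
    for v, parent in reversed(order):
        if v in labels:
            allowed = taxon_state_sets[labels[v]]
            if not allowed:
                raise ValueError(f"empty state set for taxon {labels[v]!r}")
            vec = np.full(n_states, _INF, dtype=np.int64)
            vec[list(allowed)] = 0
            g[v] = vec
            continue
        acc = np.zeros(n_states, dtype=np.int64)
        for u in adj[v]:
            if u == parent:
                continue
            acc = acc + np.min(cost + g[u][None, :], axis=1)
        g[v] = acc
    return int(g[order[0][0]].min())


# ---------------------------------------------------------------------------
# Fitch (unordered, inapplicable treated as full ambiguity)
# ---------------------------------------------------------------------------

def _leaf_mask(cell: CellValue, n_states: int, code_bit: Mapping[int, int]) -> int:
    full = (1 << n_states) - 1
    if cell is MISSING or cell is INAPPLICABLE:
        return full
    if isinstance(cell, frozenset):
        m = 0
        for s in cell:
            m |= 1 << code_bit[s]
        return m
    return 1 << code_bit[cell]


def _char_masks(
    character: Character, cells: Mapping[str, CellValue]
) -> Dict[str, int]:
    code_bit = {s: i for i, s in enumerate(character.state_codes)}
    return {
        lab: _leaf_mask(c, len(character.state_codes), code_bit)
        for lab, c in cells.items()
    }


def masks_to_sets(masks: Mapping[str, int], n_states: int) -> Dict[str, FrozenSet[int]]:
    return {
        lab: frozenset(i for i in range(n_states) if m >> i & 1)
        for lab, m in masks.items()
    }


@dataclass
class _UnitCost:
    cost_int: np.ndarray
    cost_scale: int = 1


def _unit_composite(character: Character) -> _UnitCost:
    n = len(character.state_codes)
    cost = np.ones((n, n), dtype=np.int64) - np.eye(n, dtype=np.int64)
    return _UnitCost(cost)


def fitch_steps(
    tree: PhyloTree,
    character: Character,
    cells: Mapping[str, CellValue],
) -> int:
    """Minimum unordered-parsimony steps, treating missing, inapplicable and
    polymorphic cells as ambiguity sets (inapplicable = all states)."""
    for lab in tree.leaf_set:
        if lab not in cells:
            raise ValueError(f"no cell for leaf {lab!r}")
    masks = _char_masks(character, cells)
    if tree.n_leaves <= 2:
        vals = [masks[lab] for lab in tree.leaf_set]
        return 0 if len(vals) < 2 or (vals[0] & vals[1]) else 1
    order = _rooted_order(tree)
    if tree.is_binary:
        return _fitch_masks(tree.adjacency, tree.leaf_ids, order, masks)
    unit = _unit_composite(character)
    sets = masks_to_sets(masks, len(character.state_codes))
    return _sankoff_masks(tree.adjacency, tree.leaf_ids, order, unit.cost_int, sets)


# ---------------------------------------------------------------------------
# Sankoff
# ---------------------------------------------------------------------------

def sankoff_cost(tree: PhyloTree, composite: CompositeCharacter) -> Fraction:
    """Minimum total transformation cost of the composite on the tree."""
    if tree.n_leaves == 2:
        a, b = sorted(tree.leaf_set)
        best = min(
            composite.cost_int[i, j]
            for i in composite.taxon_state_sets[a]
            for j in composite.taxon_state_sets[b]
        )
        return Fraction(int(best), composite.cost_scale)
    order = _rooted_order(tree)
    raw = _sankoff_masks(
        tree.adjacency, tree.leaf_ids, order,
        composite.cost_int, composite.taxon_state_sets,
    )
    return Fraction(raw, composite.cost_scale)


def optimal_leaf_assignments(
    tree: PhyloTree, composite: CompositeCharacter
) -> Dict[str, FrozenSet[int]]:
    """For every taxon, the composite states it takes in at least one
    minimum-cost reconstruction (used to audit ambiguous scorings)."""
    cost = composite.cost_int
    n_states = cost.shape[0]
    labels = tree.leaf_ids
    order = _rooted_order(tree)
    root = order[0][0]
    children: Dict[int, List[int]] = {v: [] for v, _ in order}
    for v, parent in order:
        if parent >= 0:
            children[parent].append(v)
    g: Dict[int, np.ndarray] = {}
    for v, _ in reversed(order):
        if v in labels:
            vec = np.full(n_states, _INF, dtype=np.int64)
            vec[list(composite.taxon_state_sets[labels[v]])] = 0
            g[v] = vec
        else:
            acc = np.zeros(n_states, dtype=np.int64)
            for u in children[v]:
                acc = acc + np.min(cost + g[u][None, :], axis=1)
            g[v] = acc
    best = g[root].min()
    feasible: Dict[int, np.ndarray] = {root: g[root] == best}
    for v, parent in order:
        if parent < 0:
            continue
        child_min = np.min(cost + g[v][None, :], axis=1)
        ok = np.zeros(n_states, dtype=bool)
        for s in np.nonzero(feasible[parent])[0]:
            ok |= (cost[s, :] + g[v]) == child_min[s]
        feasible[v] = ok
    return {
        lab: frozenset(int(i) for i in np.nonzero(feasible[v])[0])
        for v, lab in labels.items()
    }


# ---------------------------------------------------------------------------
# Minimum possible cost (homoplasy baseline)
# ---------------------------------------------------------------------------

def _steiner_min(cost: np.ndarray, terminals: Sequence[int]) -> int:
    """Exact minimum Steiner-tree cost over the (metric) state graph
    connecting the terminals (Dreyfus-Wagner)."""
    terms = sorted(set(terminals))
    t = len(terms)
    if t <= 1:
        return 0
    if t == 2:
        return int(cost[terms[0], terms[1]])
    n = cost.shape[0]
    q = terms[1:]
    full = (1 << len(q)) - 1
    dp = np.full((full + 1, n), _INF, dtype=np.int64)
    for i, term in enumerate(q):
        dp[1 << i] = cost[term]
    for s in range(1, full + 1):
        if s & (s - 1) == 0:
            continue
        sub = (s - 1) & s
        while sub:
            if sub <= (s ^ sub):  # consider each split once
                np.minimum(dp[s], dp[sub] + dp[s ^ sub], out=dp[s])
            sub = (sub - 1) & s
        dp[s] = np.min(cost + dp[s][None, :], axis=1)
    return int(dp[full][terms[0]])


def min_possible_cost(
    unit: Union[Character, CompositeCharacter],
    cells: Optional[Mapping[str, CellValue]] = None,
    steiner_terminal_cap: int = 10,
) -> Fraction:
    """Tree-independent lower bound on the unit's cost.

    For an unordered character: (number of definitely observed states - 1)
    unweighted steps.  For a composite: the exact Steiner connection cost of
    the forced (unambiguous) taxon states under the step matrix, or a
    minimum-spanning-tree bound when there are too many terminals.
    """
    if isinstance(unit, Character):
        if cells is None:
            raise ValueError("cells required for an independent character")
        observed = {c for c in cells.values() if isinstance(c, int)}
        return Fraction(max(len(observed) - 1, 0))
    terminals = sorted(
        {next(iter(s)) for s in unit.taxon_state_sets.values() if len(s) == 1}
    )
    if len(terminals) <= 1:
        return Fraction(0)
    if len(terminals) <= steiner_terminal_cap:
        raw = _steiner_min(unit.cost_int, terminals)
    else:  # MST over the metric closure; may overshoot, callers clamp h >= 0
        from scipy.sparse.csgraph import minimum_spanning_tree

        sub = unit.cost_int[np.ix_(terminals, terminals)]
        raw = int(round(minimum_spanning_tree(sub).sum()))
    return Fraction(raw, unit.cost_scale)


# ---------------------------------------------------------------------------
# Implied weighting
# ---------------------------------------------------------------------------

def iw_contribution(h: float, k: float, n: int = 1) -> float:
    """Fit cost n * (hbar/(hbar+k)), hbar = h/n: 0 at h=0, concave and
    strictly increasing in h."""
    if k <= 0:
        raise ValueError("k must be positive")
    if h < 0:
        raise ValueError("homoplasy cannot be negative")
    if n < 1:
        raise ValueError("member count must be >= 1")
    hbar = h / n
    return n * (hbar / (hbar + k)) if hbar else 0.0


def compute_sk(h_max: float, N: float = 15.0) -> float:
    """k such that a zero-homoplasy character outweighs the most homoplastic
    one exactly N-fold: k = h_max / (N - 1)."""
    if N <= 1:
        raise ValueError("ratio N must exceed 1")
    if h_max <= 0:
        raise ValueError("dataset is homoplasy-free; implied weighting is pointless")
    return h_max / (N - 1)


# ---------------------------------------------------------------------------
# Whole-tree scoring
# ---------------------------------------------------------------------------

@dataclass
class UnitScore:
    label: str
    members: Tuple[int, ...]
    steps: Fraction
    min_steps: Fraction
    homoplasy: Fraction  # raw step units (weight-normalized for composites)
    contribution: float

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class ScoreReport:
    per_character: List[UnitScore]
    total_score: float
    scheme: WeightingScheme

    def to_tsv(self) -> str:
        lines = ["unit\tcharacters\tsteps\tmin\thomoplasy\tcontribution"]
        for u in self.per_character:
            chars = " ".join(str(m + 1) for m in u.members)
            lines.append(
                f"{u.label}\t{chars}\t{float(u.steps):g}\t{float(u.min_steps):g}"
                f"\t{float(u.homoplasy):g}\t{u.contribution:g}"
            )
        lines.append(f"TOTAL\t\t\t\t\t{self.total_score:g}")
        return "\n".join(lines) + "\n"


class ParsimonyScorer:
    """Pre-digests a matrix (optionally with composites) for fast repeated
    tree scoring during searches.

    ``char_multipliers`` scales individual original characters (used by
    bootstrap resampling and the ratchet); a multiplier of 0 removes the
    character's cost contribution entirely.
    """

    def __init__(
        self,
        matrix: CharacterMatrix,
        graph: Optional[DependencyGraph] = None,
        scheme: WeightingScheme = EW,
        use_composites: bool = False,
        state_space_cap: int = 4096,
        char_multipliers: Optional[Mapping[int, int]] = None,
    ) -> None:
        self.matrix = matrix
        self.graph = graph if graph is not None else DependencyGraph()
        self.scheme = scheme
        self.use_composites = use_composites
        self.state_space_cap = state_space_cap
        mult = dict(char_multipliers or {})
        self._mult = mult

        self._composites: List[CompositeCharacter] = []
        self._independent: List[Character] = []
        if use_composites:
            scaled = _scaled_matrix(matrix, mult)
            for comp in find_complexes(self.graph, matrix.n_characters):
                if len(comp) >= 2:
                    if all(mult.get(m, 1) == 0 for m in comp):
                        continue
                    self._composites.append(
                        build_composite(
                            scaled, self.graph, comp,
                            cap=state_space_cap,
                            allow_zero_weight=bool(mult),
                        )
                    )
                else:
                    (m,) = comp
                    if mult.get(m, 1) != 0:
                        self._independent.append(matrix.characters[m])
        else:
            self._independent = [
                ch for ch in matrix.characters if mult.get(ch.index, 1) != 0
            ]

        self._ind_data = []
        for ch in self._independent:
            cells = matrix.column(ch.index)
            masks = _char_masks(ch, cells)
            w = ch.weight * mult.get(ch.index, 1)
            self._ind_data.append(
                (
                    ch,
                    masks,
                    w,
                    min_possible_cost(ch, cells),
                    _unit_composite(ch),
                    masks_to_sets(masks, len(ch.state_codes)),
                )
            )
        self._comp_min = [min_possible_cost(c) for c in self._composites]
        taxa = matrix.taxon_labels
        self._comp_batch = _build_batch(
            [c.cost_int for c in self._composites],
            [c.taxon_state_sets for c in self._composites],
            taxa,
        )
        self._ind_batch = _build_batch(
            [d[4].cost_int for d in self._ind_data],
            [d[5] for d in self._ind_data],
            taxa,
        )

    def _comp_costs(self, adj, labels, order) -> List[Fraction]:
        if not self._composites:
            return []
        raw = _batched_sankoff(adj, labels, order, self._comp_batch)
        return [
            Fraction(int(r), c.cost_scale)
            for r, c in zip(raw, self._composites)
        ]

    def _ind_steps(self, adj, labels, order, binary: bool) -> List[int]:
        if not self._ind_data:
            return []
        if binary:
            return [
                _fitch_masks(adj, labels, order, d[1]) for d in self._ind_data
            ]
        return [int(r) for r in _batched_sankoff(adj, labels, order, self._ind_batch)]

    @property
    def n_units(self) -> int:
        return len(self._ind_data) + len(self._composites)

    # -- unit-level scores -------------------------------------------------

    def unit_scores(self, tree: PhyloTree) -> List[UnitScore]:
        k = self.scheme.k if self.scheme.mode == "IW" else None
        adj, labels = tree.adjacency, tree.leaf_ids
        order = _rooted_order(tree)
        binary = tree.is_binary
        out: List[UnitScore] = []
        ind_steps = self._ind_steps(adj, labels, order, binary)
        for (ch, masks, w, min_steps, unit, sets), raw in zip(
            self._ind_data, ind_steps
        ):
            steps = Fraction(raw)
            h = max(steps - min_steps, Fraction(0))
            contribution = (
                float(w * steps) if k is None else iw_contribution(float(h), k, 1)
            )
            out.append(
                UnitScore(
                    label=f"c{ch.index + 1}",
                    members=(ch.index,),
                    steps=steps,
                    min_steps=min_steps,
                    homoplasy=h,
                    contribution=contribution,
                )
            )
        comp_costs = self._comp_costs(adj, labels, order)
        for comp, min_cost, cost in zip(
            self._composites, self._comp_min, comp_costs
        ):
            h = max(cost - min_cost, Fraction(0)) / comp.weight_scale
            n = comp.n_members
            contribution = (
                float(cost) if k is None else iw_contribution(float(h), k, n)
            )
            out.append(
                UnitScore(
                    label="x" + "+".join(str(m + 1) for m in comp.members),
                    members=comp.members,
                    steps=cost,
                    min_steps=min_cost,
                    homoplasy=h,
                    contribution=contribution,
                )
            )
        return out

    # -- totals ------------------------------------------------------------

    def ew_total(self, tree: PhyloTree) -> Fraction:
        adj, labels = tree.adjacency, tree.leaf_ids
        order = _rooted_order(tree)
        binary = tree.is_binary
        total = Fraction(0)
        for (ch, masks, w, _, unit, sets), steps in zip(
            self._ind_data, self._ind_steps(adj, labels, order, binary)
        ):
            total += w * steps
        for cost in self._comp_costs(adj, labels, order):
            total += cost
        return total

    def iw_total(self, tree: PhyloTree) -> float:
        """Summed fit cost under the active k, without report overhead."""
        k = self.scheme.k
        adj, labels = tree.adjacency, tree.leaf_ids
        order = _rooted_order(tree)
        binary = tree.is_binary
        total = 0.0
        for (ch, masks, w, min_steps, unit, sets), steps in zip(
            self._ind_data, self._ind_steps(adj, labels, order, binary)
        ):
            h = steps - float(min_steps)
            if h > 0:
                total += h / (h + k)
        for comp, min_cost, cost in zip(
            self._composites, self._comp_min,
            self._comp_costs(adj, labels, order),
        ):
            h = (float(cost) - float(min_cost)) / float(comp.weight_scale)
            if h > 0:
                n = comp.n_members
                hbar = h / n
                total += n * hbar / (hbar + k)
        return round(total, 10)

    def total(self, tree: PhyloTree) -> Union[Fraction, float]:
        """The quantity minimized by a search under the active scheme."""
        if self.scheme.mode == "EW":
            return self.ew_total(tree)
        return self.iw_total(tree)

    def report(self, tree: PhyloTree) -> ScoreReport:
        units = self.unit_scores(tree)
        if self.scheme.mode == "EW":
            total = float(sum(u.contribution for u in units))
        else:
            total = round(sum(u.contribution for u in units), 10)
        return ScoreReport(per_character=units, total_score=total, scheme=self.scheme)

    def max_homoplasy(self, trees: Sequence[PhyloTree]) -> float:
        """Largest per-constituent homoplasy over the given trees (used to
        derive sk from the best EW trees)."""
        h_max = 0.0
        for t in trees:
            for u in self.unit_scores(t):
                h_max = max(h_max, float(u.homoplasy) / u.n_members)
        return h_max

    def with_scheme(self, scheme: WeightingScheme) -> "ParsimonyScorer":
        clone = object.__new__(ParsimonyScorer)
        clone.__dict__ = dict(self.__dict__)
        clone.scheme = scheme
        return clone

    def reweighted(self, char_multipliers: Mapping[int, int]) -> "ParsimonyScorer":
        return ParsimonyScorer(
            self.matrix,
            self.graph,
            self.scheme,
            self.use_composites,
            self.state_space_cap,
            char_multipliers=char_multipliers,
        )


def _scaled_matrix(
    matrix: CharacterMatrix, mult: Mapping[int, int]
) -> CharacterMatrix:
    """Copy of the matrix with multiplier-scaled weights (0 allowed, bypassing
    the Character validator; used only inside scorer construction)."""
    if not mult:
        return matrix
    chars = []
    for ch in matrix.characters:
        m = mult.get(ch.index, 1)
        if m == 1:
            chars.append(ch)
        else:
            clone = object.__new__(Character)
            object.__setattr__(clone, "index", ch.index)
            object.__setattr__(clone, "statement", ch.statement)
            object.__setattr__(clone, "char_type", ch.char_type)
            object.__setattr__(clone, "state_codes", ch.state_codes)
            object.__setattr__(clone, "weight", ch.weight * m)
            chars.append(clone)
    out = object.__new__(CharacterMatrix)
    out.taxon_labels = list(matrix.taxon_labels)
    out.characters = chars
    out.cells = matrix.cells
    out.source_commands = list(matrix.source_commands)
    return out


def score_tree(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    graph: Optional[DependencyGraph] = None,
    scheme: WeightingScheme = EW,
    use_composites: bool = False,
) -> ScoreReport:
    """One-shot scoring convenience wrapper around :class:`ParsimonyScorer`."""
    return ParsimonyScorer(matrix, graph, scheme, use_composites).report(tree)
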