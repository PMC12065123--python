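"""Heuristic search for minimum-score trees.

The driver mirrors TNT's ``xmult``-style protocol: random-addition starts
followed by branch swapping (NNI/SPR/TBR), optionally perturbed by a
parsimony ratchet (temporary reweighting of a random character subset) and by
drift (bounded acceptance of slightly worse trees), repeated over replicates
until the best score has been hit independently a required number of times.
All stochastic choices draw from one seeded generator, so every search is
replayable.  Found trees can be pooled in a :class:`TreeCollection` and
cross-checked with TBR rounds until closure (no analysis adds a new tree).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .dependency_model import DependencyGraph
from .matrix_io import CharacterMatrix
from .parsimony_scoring import ParsimonyScorer, WeightingScheme
from .trees import PhyloTree, TreeCollection


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the multistart driver.

    The defaults mirror the thorough protocol (20 replicates, stop after 10
    independent hits, 100 ratchet and 100 drift iterations, TBR swapping);
    composite analyses typically use the lighter ``replicates=5,
    hits_required=2`` preset because Sankoff scoring is far more expensive.
    """

    replicates: int = 20
    hits_required: int = 10
    ratchet_iterations: int = 100
    drift_iterations: int = 100
    swap_mode: str = "TBR"
    rng_seed: int = 0
    collapse_rule: str = "min-length-zero"  # or "none"
    ratchet_fraction: float = 0.25
    ratchet_factor: int = 2
    drift_tolerance: float = 0.02

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if min(self.hits_required, self.ratchet_iterations, self.drift_iterations) < 0:
            raise ValueError("counts must be >= 0")
        if self.swap_mode not in ("NNI", "SPR", "TBR"):
            raise ValueError("swap_mode must be NNI, SPR or TBR")
        if self.collapse_rule not in ("min-length-zero", "none"):
            raise ValueError("unknown collapse rule")


FAST = SearchConfig(replicates=5, hits_required=2, ratchet_iterations=0,
                    drift_iterations=0)


# ---------------------------------------------------------------------------
# Rearrangement neighbourhoods
# ---------------------------------------------------------------------------

def _reachable(adj: Mapping[int, List[int]], start: int) -> Set[int]:
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for u in adj[v]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return seen


def _splice(adj: Dict[int, List[int]], labels: Mapping[int, str], v: int) -> None:
    if v not in labels and len(adj[v]) == 2:
        a, b = adj[v]
        adj[a] = [b if x == v else x for x in adj[a]]
        adj[b] = [a if x == v else x for x in adj[b]]
        del adj[v]


def nni_neighbors(tree: PhyloTree) -> Iterator[PhyloTree]:
    """The two nearest-neighbour interchanges across every internal edge."""
    labels = tree.leaf_ids
    for u, v in tree.internal_edges():
        u_sub = [x for x in tree.adjacency[u] if x != v]
        v_sub = [x for x in tree.adjacency[v] if x != u]
        b = u_sub[1]
        for c in v_sub:
            adj = {k: list(nb) for k, nb in tree.adjacency.items()}
            adj[u] = [c if x == b else x for x in adj[u]]
            adj[v] = [b if x == c else x for x in adj[v]]
            adj[b] = [v if x == u else x for x in adj[b]]
            adj[c] = [u if x == v else x for x in adj[c]]
            yield PhyloTree(adj, labels)


def spr_neighbors(tree: PhyloTree) -> Iterator[PhyloTree]:
    """Subtree pruning and regrafting over all directed edges."""
    labels = tree.leaf_ids
    counter = max(tree.adjacency) + 1
    for p in tree.adjacency:
        for c in tree.adjacency[p]:
            # prune the subtree rooted at c (away from p)
            adj = {k: list(nb) for k, nb in tree.adjacency.items()}
            adj[p].remove(c)
            adj[c].remove(p)
            pruned = _reachable(adj, c)
            if len(pruned) >= len(adj) - 1:
                continue  # nothing left to regraft onto
            _splice(adj, labels, p)
            remaining = set(adj) - pruned
            if len(remaining) < 2:
                continue
            edges = [
                (x, y)
                for x in remaining
                for y in adj[x]
                if x < y and y in remaining
            ]
            for x, y in edges:
                adj2 = {k: list(nb) for k, nb in adj.items()}
                mid = counter
                adj2[x] = [mid if t == y else t for t in adj2[x]]
                adj2[y] = [mid if t == x else t for t in adj2[y]]
                adj2[mid] = [x, y, c]
                adj2[c] = adj2[c] + [mid]
                yield PhyloTree(adj2, labels)


def tbr_neighbors(tree: PhyloTree) -> Iterator[PhyloTree]:
    """Tree bisection and reconnection over all edges and reconnection pairs."""
    labels = tree.leaf_ids
    counter = max(tree.adjacency) + 1
    for u, v in tree.edges():
        adj = {k: list(nb) for k, nb in tree.adjacency.items()}
        adj[u].remove(v)
        adj[v].remove(u)
        comp_u = _reachable(adj, u)
        comp_v = _reachable(adj, v)
        for w in (u, v):
            _splice(adj, labels, w)
        comp_u &= set(adj)
        comp_v &= set(adj)

        def attach_points(comp: Set[int], origin: int):
            if len(comp) == 1:
                return [None]
            return [
                (x, y) for x in comp for y in adj[x] if x < y and y in comp
            ]

        pts_u = attach_points(comp_u, u)
        pts_v = attach_points(comp_v, v)
        for e1 in pts_u:
            for e2 in pts_v:
                adj2 = {k: list(nb) for k, nb in adj.items()}
                ends = []
                nxt = counter
                for e, comp, origin in ((e1, comp_u, u), (e2, comp_v, v)):
                    if e is None:
                        ends.append(next(iter(comp)))
                    else:
                        x, y = e
                        mid = nxt
                        nxt += 1
                        adj2[x] = [mid if t == y else t for t in adj2[x]]
                        adj2[y] = [mid if t == x else t for t in adj2[y]]
                        adj2[mid] = [x, y]
                        ends.append(mid)
                a, b = ends
                adj2[a] = adj2[a] + [b]
                adj2[b] = adj2[b] + [a]
                yield PhyloTree(adj2, labels)


_NEIGHBORHOODS = {"NNI": nni_neighbors, "SPR": spr_neighbors, "TBR": tbr_neighbors}


# ---------------------------------------------------------------------------
# Random addition and local search
# ---------------------------------------------------------------------------

def random_addition_tree(
    matrix: CharacterMatrix, scorer: ParsimonyScorer, seed: int
) -> PhyloTree:
    """Stepwise addition in seeded-random taxon order, each taxon inserted at
    its locally best position; deterministic for a given seed."""
    taxa = list(matrix.taxon_labels)
    if len(taxa) < 4:
        raise ValueError("random addition requires at least 4 taxa")
    rng = np.random.default_rng(seed)
    order = [taxa[i] for i in rng.permutation(len(taxa))]
    first = sorted(order[:3])
    adj: Dict[int, List[int]] = {0: [1], 1: [0, 2, 3], 2: [1], 3: [1]}
    labels = {0: first[0], 2: first[1], 3: first[2]}
    counter = 4
    tree = PhyloTree(adj, labels)
    for taxon in order[3:]:
        sub_scorer = _restricted(scorer, set(tree.leaf_ids.values()) | {taxon})
        best: Optional[PhyloTree] = None
        best_score = None
        for x, y in tree.edges():
            adj2 = {k: list(nb) for k, nb in tree.adjacency.items()}
            mid, leaf = counter, counter + 1
            adj2[x] = [mid if t == y else t for t in adj2[x]]
            adj2[y] = [mid if t == x else t for t in adj2[y]]
            adj2[mid] = [x, y, leaf]
            adj2[leaf] = [mid]
            labels2 = dict(tree.leaf_ids)
            labels2[leaf] = taxon
            cand = PhyloTree(adj2, labels2)
            s = sub_scorer.total(cand)
            if best_score is None or s < best_score:
                best, best_score = cand, s
        tree = best
        counter += 2
    return tree


def _restricted(scorer: ParsimonyScorer, taxa: Set[str]) -> ParsimonyScorer:
    """Scorer view over a taxon subset (for stepwise addition)."""
    if taxa == set(scorer.matrix.taxon_labels):
        return scorer
    sub_rows = [
        list(row)
        for lab, row in zip(scorer.matrix.taxon_labels, scorer.matrix.cells)
        if lab in taxa
    ]
    sub_labels = [lab for lab in scorer.matrix.taxon_labels if lab in taxa]
    sub = CharacterMatrix(
        sub_labels, list(scorer.matrix.characters), sub_rows,
        list(scorer.matrix.source_commands),
    )
    return ParsimonyScorer(
        sub, scorer.graph, scorer.scheme, scorer.use_composites,
        scorer.state_space_cap, char_multipliers=scorer._mult or None,
    )


@dataclass
class SwapResult:
    tree: PhyloTree
    score: object
    all_best: FrozenSet[PhyloTree]


def swap_to_local_optimum(
    tree: PhyloTree, scorer: ParsimonyScorer, mode: str = "TBR"
) -> SwapResult:
    """Steepest-descent branch swapping until no rearrangement of the given
    mode improves the score; ties at the final score are all retained."""
    gen = _NEIGHBORHOODS[mode]
    current = tree
    score = scorer.total(tree)
    while True:
        best_nb = None
        best_score = score
        ties: Set[PhyloTree] = set()
        seen: Set[PhyloTree] = {current}
        for nb in gen(current):
            if nb in seen:
                continue
            seen.add(nb)
            s = scorer.total(nb)
            if s < best_score:
                best_nb, best_score = nb, s
                ties = set()
            elif s == score and best_nb is None:
                ties.add(nb)
        if best_nb is None:
            return SwapResult(current, score, frozenset({current} | ties))
        current, score = best_nb, best_score


def ratchet(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    scorer: ParsimonyScorer,
    iterations: int,
    seed: int,
    fraction: float = 0.25,
    factor: int = 2,
    swap_mode: str = "TBR",
) -> List[PhyloTree]:
    """Parsimony ratchet: per iteration, upweight a random ~``fraction`` of
    the characters by ``factor``, swap, restore the weights, swap again.
    Returns the distinct best trees at the best score seen."""
    rng = np.random.default_rng(seed)
    best = {tree}
    best_score = scorer.total(tree)
    current = tree
    n_char = matrix.n_characters
    for _ in range(iterations):
        subset = rng.random(n_char) < fraction
        mult = {i: factor for i in np.nonzero(subset)[0]}
        perturbed = scorer.reweighted(mult)
        wander = swap_to_local_optimum(current, perturbed, swap_mode).tree
        result = swap_to_local_optimum(wander, scorer, swap_mode)
        current = result.tree
        if result.score < best_score:
            best_score = result.score
            best = set(result.all_best)
        elif result.score == best_score:
            best |= set(result.all_best)
    return sorted(best, key=lambda t: t.to_newick())


def drift(
    tree: PhyloTree,
    scorer: ParsimonyScorer,
    iterations: int,
    seed: int,
    tolerance: float = 0.02,
    swap_mode: str = "TBR",
) -> List[PhyloTree]:
    """Drift perturbation: accept random rearrangements no worse than the
    current score times (1 + tolerance) for a fixed number of moves, then
    re-optimize.  Returns the distinct best trees seen."""
    rng = np.random.default_rng(seed)
    best = {tree}
    best_score = scorer.total(tree)
    current = tree
    slack = float(best_score) * tolerance if float(best_score) > 0 else tolerance
    for _ in range(iterations):
        neighbors = list(nni_neighbors(current))
        nb = neighbors[rng.integers(len(neighbors))]
        s = scorer.total(nb)
        if float(s) <= float(best_score) + slack:
            current = nb
        if s < best_score:
            best_score, best = s, {nb}
        elif s == best_score:
            best.add(nb)
    result = swap_to_local_optimum(current, scorer, swap_mode)
    if result.score < best_score:
        return sorted(result.all_best, key=lambda t: t.to_newick())
    if result.score == best_score:
        best |= set(result.all_best)
    return sorted(best, key=lambda t: t.to_newick())


# ---------------------------------------------------------------------------
# Collapse rule
# ---------------------------------------------------------------------------

def collapse_zero_length(tree: PhyloTree, scorer: ParsimonyScorer) -> PhyloTree:
    """Collapse internal edges whose minimum possible length is zero, i.e.
    whose contraction does not worsen the total score (TNT's default intent).
    """
    score = scorer.total(tree)
    current = tree
    changed = True
    while changed:
        changed = False
        for split in sorted(current.bipartitions, key=sorted):
            reduced = PhyloTree.from_splits(
                current.taxa,
                [b for b in current.bipartitions if b != split],
            )
            if scorer.total(reduced) == score:
                current = reduced  # contraction verified score-neutral
                changed = True
                break
    return current


# ---------------------------------------------------------------------------
# Multistart driver
# ---------------------------------------------------------------------------

@dataclass
class SearchResult:
    trees: List[PhyloTree]
    score: object
    replicates_run: int
    hits: int


def multistart_search(
    matrix: CharacterMatrix,
    graph: Optional[DependencyGraph],
    scheme: WeightingScheme,
    config: SearchConfig,
    use_composites: bool = False,
    scorer: Optional[ParsimonyScorer] = None,
    start_trees: Sequence[PhyloTree] = (),
) -> SearchResult:
    """Replicated RAS + swap (+ ratchet/drift) search; stops early when the
    best score has been hit independently ``hits_required`` times.  Returns
    all distinct best trees, deduplicated after applying the collapse rule."""
    if scorer is None:
        scorer = ParsimonyScorer(matrix, graph, scheme, use_composites)
    else:
        scorer = scorer.with_scheme(scheme)
    rng = np.random.default_rng(config.rng_seed)
    best_score = None
    best: Set[PhyloTree] = set()
    hits = 0
    reps = 0
    starts: List[Optional[PhyloTree]] = list(start_trees) or [None] * config.replicates
    for rep, start in enumerate(starts):
        reps += 1
        rep_seed = int(rng.integers(2**31 - 1))
        tree = (
            start
            if start is not None
            else random_addition_tree(matrix, scorer, rep_seed)
        )
        result = swap_to_local_optimum(tree, scorer, config.swap_mode)
        found = set(result.all_best)
        found_score = result.score
        if config.ratchet_iterations:
            for t in ratchet(
                result.tree, matrix, scorer, config.ratchet_iterations,
                rep_seed + 1, config.ratchet_fraction, config.ratchet_factor,
                config.swap_mode,
            ):
                s = scorer.total(t)
                if s < found_score:
                    found, found_score = {t}, s
                elif s == found_score:
                    found.add(t)
        if config.drift_iterations:
            for t in drift(
                result.tree, scorer, config.drift_iterations, rep_seed + 2,
                config.drift_tolerance, config.swap_mode,
            ):
                s = scorer.total(t)
                if s < found_score:
                    found, found_score = {t}, s
                elif s == found_score:
                    found.add(t)
        if best_score is None or found_score < best_score:
            best_score = found_score
            best = set(found)
            hits = 1
        elif found_score == best_score:
            best |= found
            hits += 1
        if config.hits_required and hits >= config.hits_required:
            break
    trees = sorted(best, key=lambda t: t.to_newick())
    if config.collapse_rule == "min-length-zero":
        collapsed = {collapse_zero_length(t, scorer) for t in trees}
        trees = sorted(collapsed, key=lambda t: t.to_newick())
    return SearchResult(trees=trees, score=best_score, replicates_run=reps, hits=hits)


def update_tree_collection(
    collection: TreeCollection,
    new_mpts: Iterable[PhyloTree],
    scorer: ParsimonyScorer,
    label: str,
    swap_mode: str = "TBR",
) -> Tuple[TreeCollection, int]:
    """Add non-duplicate MPTs, then run one TBR round seeded from collection
    members under the current scorer, adding equal-or-better distinct trees.
    Looping analyses until a full pass adds zero trees reaches closure."""
    added = 0
    for t in new_mpts:
        added += collection.add(t, label)
    if len(collection):
        best_score = min(scorer.total(t) for t in collection)
        for t in list(collection):
            result = swap_to_local_optimum(t, scorer, swap_mode)
            if result.score <= best_score:
                for cand in result.all_best:
                    added += collection.add(cand, f"{label}+tbr")
    return collection, added


# ---------------------------------------------------------------------------
# Consensus and bootstrap
# ---------------------------------------------------------------------------

def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """The tree displaying exactly the bipartitions shared by every input."""
    if not trees:
        raise ValueError("need at least one tree")
    leafset = trees[0].leaf_set
    for t in trees[1:]:
        if t.leaf_set != leafset:
            raise ValueError("trees have mismatched leaf sets")
    shared = frozenset.intersection(*(t.bipartitions for t in trees))
    return PhyloTree.from_splits(leafset, shared)


def bootstrap_support(
    matrix: CharacterMatrix,
    graph: Optional[DependencyGraph],
    scheme: WeightingScheme,
    pseudo_replicates: int,
    config: SearchConfig,
    seed: int,
    use_composites: bool = False,
) -> Dict[FrozenSet[str], float]:
    """Bipartition frequencies (percent) over searches on matrices resampled
    from the ORIGINAL characters with replacement; composite characters are
    rebuilt per replicate from the resampled weights."""
    if pseudo_replicates < 1:
        raise ValueError("pseudo_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    n_char = matrix.n_characters
    counts: Dict[FrozenSet[str], int] = {}
    for _ in range(pseudo_replicates):
        draws = rng.integers(0, n_char, size=n_char)
        mult = {i: 0 for i in range(n_char)}
        for d in draws:
            mult[int(d)] += 1
        scorer = ParsimonyScorer(
            matrix, graph, scheme, use_composites, char_multipliers=mult
        )
        rep_config = replace(
            config, rng_seed=int(rng.integers(2**31 - 1)),
        )
        result = multistart_search(
            matrix, graph, scheme, rep_config,
            use_composites=use_composites, scorer=scorer,
        )
        for split in strict_consensus(result.trees).bipartitions:
            counts[split] = counts.get(split, 0) + 1
    return {
        split: 100.0 * c / pseudo_replicates for split, c in counts.items()
    }
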