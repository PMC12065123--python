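"""Robinson-Foulds congruence analysis across analysis batches.

Distances are normalized Robinson-Foulds values: the count of bipartitions
present in exactly one tree, divided by 2(n-3), the total number of internal
bipartitions of two fully resolved trees on n leaves.  Multifurcating
consensus trees are not compared, only MPTs.  The congruence-based selection
combines the anchor analyses' MPTs (typically the two sk-IW runs) with, from
every other batch, the tree(s) closest to any anchor, and returns their
strict consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .trees import PhyloTree
from .tree_search import strict_consensus


def display_round(value: float, places: int = 2) -> float:
    """Half-up rounding for displayed distances (0.125 prints as 0.13)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def nrf_distance(t1: PhyloTree, t2: PhyloTree) -> float:
    """Normalized Robinson-Foulds distance in [0, 1]: 0 iff topologically
    identical, 1 iff no internal bipartition is shared."""
    if t1.leaf_set != t2.leaf_set:
        raise ValueError("trees have different leaf sets")
    n = t1.n_leaves
    if n < 4:
        raise ValueError("nRF requires at least 4 leaves")
    rf = len(t1.bipartitions ^ t2.bipartitions)
    return rf / (2 * (n - 3))


@dataclass
class DistanceMatrix:
    """Labelled square table of pairwise nRF distances."""

    labels: List[str]
    values: np.ndarray
    rounding: int = 2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("labels do not match matrix shape")

    def rounded(self) -> np.ndarray:
        out = np.vectorize(lambda v: display_round(v, self.rounding))
        return out(self.values) if self.values.size else self.values

    def max_distance(self) -> float:
        if len(self.labels) < 2:
            return 0.0
        return float(np.max(self.values))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def distance_matrix(
    tree_batches: Sequence[Tuple[str, Sequence[PhyloTree]]],
    rounding: int = 2,
) -> DistanceMatrix:
    """Pairwise nRF over the concatenated, deduplicated trees of all batches.

    Labels are ``<batch>#<i>``; a tree occurring in several batches keeps the
    label of its first occurrence (provenance of later batches is appended
    with ``=``).
    """
    trees: List[PhyloTree] = []
    labels: List[str] = []
    index: Dict[PhyloTree, int] = {}
    for batch_label, batch in tree_batches:
        for i, t in enumerate(batch, start=1):
            name = f"{batch_label}#{i}" if len(batch) > 1 else batch_label
            if t in index:
                labels[index[t]] += f"={name}"
            else:
                index[t] = len(trees)
                trees.append(t)
                labels.append(name)
    n = len(trees)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = nrf_distance(trees[i], trees[j])
    return DistanceMatrix(labels=labels, values=values, rounding=rounding)


def internal_distance(trees: Sequence[PhyloTree]) -> float:
    """A batch's internal distance: the maximum pairwise nRF within it."""
    best = 0.0
    for i in range(len(trees)):
        for j in range(i + 1, len(trees)):
            best = max(best, nrf_distance(trees[i], trees[j]))
    return best


@dataclass
class CongruenceSelection:
    selected: List[Tuple[str, PhyloTree]]
    consensus: PhyloTree
    distances: Dict[str, float]  # per selected non-anchor tree: distance used


def select_congruent_mpts(
    batches: Mapping[str, Sequence[PhyloTree]],
    anchor_labels: Sequence[str],
) -> CongruenceSelection:
    """Keep every anchor MPT plus, per non-anchor batch, the tree(s) with the
    minimum nRF to ANY anchor tree (ties all kept); return their strict
    consensus."""
    for lab, batch in batches.items():
        if not batch:
            raise ValueError(f"batch {lab!r} is empty")
    anchors: List[Tuple[str, PhyloTree]] = []
    for lab in anchor_labels:
        if lab not in batches:
            raise ValueError(f"anchor batch {lab!r} not present")
        anchors.extend((lab, t) for t in batches[lab])
    if not anchors:
        raise ValueError("no anchor trees")
    selected = list(anchors)
    distances: Dict[str, float] = {}
    for lab, batch in batches.items():
        if lab in anchor_labels:
            continue
        dists = [
            min(nrf_distance(t, at) for _, at in anchors) for t in batch
        ]
        dmin = min(dists)
        for i, (t, d) in enumerate(zip(batch, dists), start=1):
            if d == dmin:
                name = f"{lab}#{i}" if len(batch) > 1 else lab
                selected.append((lab, t))
                distances[name] = d
    consensus = strict_consensus([t for _, t in selected])
    return CongruenceSelection(
        selected=selected, consensus=consensus, distances=distances
    )
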