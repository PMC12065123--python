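"""Unrooted phylogenetic trees and deduplicated tree collections.

Trees are stored as plain adjacency maps over integer node ids with string
labels on the leaves.  Identity is topological: two trees are equal when they
share the same leaf set and the same set of non-trivial bipartitions, which is
the notion of identity used everywhere downstream (tree collections, strict
consensus, Robinson-Foulds distances).
"""

from __future__ import annotations

import itertools
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Sequence, Tuple

import dendropy

Bipartition = FrozenSet[str]


class PhyloTree:
    """An unrooted tree over a fixed set of labelled leaves.

    Internal vertices of a fully resolved tree have degree 3; consensus trees
    may carry polytomies.  Instances are immutable and hashable.
    """

    __slots__ = ("_adj", "_labels", "_bips", "_hash")

    def __init__(
        self,
        adjacency: Mapping[int, Iterable[int]],
        leaf_labels: Mapping[int, str],
    ) -> None:
        self._adj: Dict[int, Tuple[int, ...]] = {
            v: tuple(nb) for v, nb in adjacency.items()
        }
        self._labels: Dict[int, str] = dict(leaf_labels)
        labels = list(self._labels.values())
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dup}")
        for v, nbs in self._adj.items():
            deg = len(nbs)
            if deg == 1 and v not in self._labels:
                raise ValueError(f"degree-1 node {v} has no leaf label")
            if deg != 1 and v in self._labels:
                raise ValueError(f"labelled node {v} has degree {deg}")
            for u in nbs:
                if v not in self._adj.get(u, ()):
                    raise ValueError("adjacency is not symmetric")
        self._bips: FrozenSet[Bipartition] | None = None
        self._hash: int | None = None

    # -- basic structure ---------------------------------------------------

    @property
    def adjacency(self) -> Dict[int, Tuple[int, ...]]:
        return dict(self._adj)

    @property
    def leaf_ids(self) -> Dict[int, str]:
        return dict(self._labels)

    @property
    def taxa(self) -> Tuple[str, ...]:
        return tuple(sorted(self._labels.values()))

    @property
    def leaf_set(self) -> FrozenSet[str]:
        return frozenset(self._labels.values())

    @property
    def n_leaves(self) -> int:
        return len(self._labels)

    @property
    def is_binary(self) -> bool:
        return all(
            len(nbs) in (1, 3) for nbs in self._adj.values()
        ) and len(self._adj) >= 2

    def degree(self, v: int) -> int:
        return len(self._adj[v])

    def edges(self) -> List[Tuple[int, int]]:
        return [(u, v) for u in self._adj for v in self._adj[u] if u < v]

    def internal_edges(self) -> List[Tuple[int, int]]:
        return [
            (u, v)
            for u, v in self.edges()
            if u not in self._labels and v not in self._labels
        ]

    # -- bipartitions and identity -----------------------------------------

    @property
    def bipartitions(self) -> FrozenSet[Bipartition]:
        """Non-trivial bipartitions, each encoded as the side that does not
        contain the alphabetically smallest taxon."""
        if self._bips is None:
            self._bips = frozenset(self._compute_bipartitions())
        return self._bips

    def _compute_bipartitions(self) -> List[Bipartition]:
        if self.n_leaves < 4:
            return []
        ref = min(self._labels.values())
        ref_id = next(v for v, lab in self._labels.items() if lab == ref)
        root = self._adj[ref_id][0]
        below: Dict[Tuple[int, int], FrozenSet[str]] = {}
        order: List[Tuple[int, int]] = []
        stack = [(root, ref_id)]
        while stack:
            v, parent = stack.pop()
            order.append((v, parent))
            for u in self._adj[v]:
                if u != parent:
                    stack.append((u, v))
        for v, parent in reversed(order):
            if v in self._labels:
                below[(v, parent)] = frozenset([self._labels[v]])
            else:
                acc: set = set()
                for u in self._adj[v]:
                    if u != parent:
                        acc |= below[(u, v)]
                below[(v, parent)] = frozenset(acc)
        n = self.n_leaves
        out = []
        for (v, parent), s in below.items():
            if v not in self._labels and 2 <= len(s) <= n - 2:
                out.append(s)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return self.leaf_set == other.leaf_set and self.bipartitions == other.bipartitions

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash((self.leaf_set, self.bipartitions))
        return self._hash

    def __repr__(self) -> str:
        return f"PhyloTree({self.to_newick()})"

    # -- construction --------------------------------------------------------

    @classmethod
    def from_splits(
        cls, taxa: Iterable[str], splits: Iterable[Bipartition] = ()
    ) -> "PhyloTree":
        """Build the (possibly multifurcating) tree displaying exactly the
        given compatible bipartitions.  Splits are given relative to the
        alphabetically smallest taxon (its side is implicit)."""
        taxa = sorted(set(taxa))
        if len(taxa) < 2:
            raise ValueError("need at least 2 taxa")
        ref = taxa[0]
        rest = set(taxa[1:])
        clusters = sorted({frozenset(s) for s in splits}, key=len, reverse=True)
        for c in clusters:
            if not c or not c <= rest:
                raise ValueError(f"split {sorted(c)} not a subset of taxa minus {ref!r}")
        for a, b in itertools.combinations(clusters, 2):
            if a & b and not (a <= b or b <= a):
                raise ValueError("incompatible splits")
        node_of: Dict[FrozenSet[str], int] = {}
        adj: Dict[int, List[int]] = {}
        labels: Dict[int, str] = {}
        counter = itertools.count()

        def new_node() -> int:
            v = next(counter)
            adj[v] = []
            return v

        root_cluster = frozenset(rest)
        root = new_node()
        node_of[root_cluster] = root
        ref_leaf = new_node()
        labels[ref_leaf] = ref
        adj[root].append(ref_leaf)
        adj[ref_leaf].append(root)
        ordered = [c for c in clusters if c != root_cluster]
        for c in ordered:
            parent = root_cluster
            for d in node_of:
                if c < d and len(d) < len(parent):
                    parent = d
            v = new_node()
            node_of[c] = v
            p = node_of[parent]
            adj[p].append(v)
            adj[v].append(p)
        for t in sorted(rest):
            best = root_cluster
            for d in node_of:
                if t in d and len(d) < len(best):
                    best = d
            leaf = new_node()
            labels[leaf] = t
            p = node_of[best]
            adj[p].append(leaf)
            adj[leaf].append(p)
        # suppress any degree-2 vertices (root over a single cluster)
        return cls._suppressed(adj, labels)

    @classmethod
    def _suppressed(
        cls, adj: Dict[int, List[int]], labels: Dict[int, str]
    ) -> "PhyloTree":
        adj = {v: list(nb) for v, nb in adj.items()}
        changed = True
        while changed:
            changed = False
            for v in list(adj):
                if v not in labels and len(adj[v]) == 2:
                    a, b = adj[v]
                    adj[a] = [b if x == v else x for x in adj[a]]
                    adj[b] = [a if x == v else x for x in adj[b]]
                    del adj[v]
                    changed = True
        return cls(adj, labels)

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
        adj: Dict[int, List[int]] = {}
        labels: Dict[int, str] = {}
        ids: Dict[object, int] = {}
        counter = itertools.count()
        for node in tree.preorder_node_iter():
            v = next(counter)
            ids[node] = v
            adj[v] = []
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise ValueError("unlabelled leaf in Newick input")
                labels[v] = node.taxon.label
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                u, v = ids[node.parent_node], ids[node]
                adj[u].append(v)
                adj[v].append(u)
        return cls._suppressed(adj, labels)

    def to_newick(self) -> str:
        """Serialize, rooted for display at the neighbour of the smallest leaf."""
        if self.n_leaves == 2:
            a, b = sorted(self._labels.values())
            return f"({a},{b});"
        ref = min(self._labels.values())
        ref_id = next(v for v, lab in self._labels.items() if lab == ref)
        root = self._adj[ref_id][0]

        def render(v: int, parent: int) -> str:
            if v in self._labels:
                return self._labels[v]
            parts = sorted(
                render(u, v) for u in self._adj[v] if u != parent
            )
            return "(" + ",".join(parts) + ")"

        parts = sorted([ref] + [render(u, root) for u in self._adj[root] if u != ref_id])
        return "(" + ",".join(parts) + ");"


def enumerate_topologies(taxa: Sequence[str]) -> Iterator[PhyloTree]:
    """All unrooted binary topologies over the taxa ((2n-5)!! of them)."""
    taxa = sorted(set(taxa))
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa to enumerate topologies")

    def build(k: int) -> Iterator[Tuple[Dict[int, List[int]], Dict[int, str], int]]:
        if k == 3:
            adj = {0: [1], 1: [0, 2, 3], 2: [1], 3: [1]}
            labels = {0: taxa[0], 2: taxa[1], 3: taxa[2]}
            yield adj, labels, 4
            return
        for adj, labels, nxt in build(k - 1):
            edges = [(u, v) for u in adj for v in adj[u] if u < v]
            for u, v in edges:
                adj2 = {x: list(nb) for x, nb in adj.items()}
                mid, leaf = nxt, nxt + 1
                adj2[u] = [mid if x == v else x for x in adj2[u]]
                adj2[v] = [mid if x == u else x for x in adj2[v]]
                adj2[mid] = [u, v, leaf]
                adj2[leaf] = [mid]
                labels2 = dict(labels)
                labels2[leaf] = taxa[k - 1]
                yield adj2, labels2, nxt + 2

    for adj, labels, _ in build(len(taxa)):
        yield PhyloTree(adj, labels)


class TreeCollection:
    """A store of trees deduplicated under unrooted topological identity,
    with provenance labels recording which analyses produced each tree."""

    def __init__(self) -> None:
        self._trees: Dict[PhyloTree, set] = {}

    def add(self, tree: PhyloTree, label: str) -> bool:
        """Add a tree; return True when it was not yet in the collection."""
        if tree in self._trees:
            self._trees[tree].add(label)
            return False
        self._trees[tree] = {label}
        return True

    def update(self, trees: Iterable[PhyloTree], label: str) -> int:
        return sum(self.add(t, label) for t in trees)

    def provenance(self, tree: PhyloTree) -> FrozenSet[str]:
        return frozenset(self._trees[tree])

    def __contains__(self, tree: PhyloTree) -> bool:
        return tree in self._trees

    def __iter__(self) -> Iterator[PhyloTree]:
        return iter(self._trees)

    def __len__(self) -> int:
        return len(self._trees)
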