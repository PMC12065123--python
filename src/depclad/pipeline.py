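"""The k-value browsing pipeline.

Per dataset the driver runs an equal-weights search, one implied-weighting
search per requested k, and a final implied-weighting search at the
automatically derived sk (weight-ratio N, default 15, with h_max measured on
the best equal-weights trees).  Every analysis deposits its MPTs in the
dataset's TreeCollection, which is then cross-checked by TBR rounds — and
cross-seeded with the other datasets' collections — until a full pass adds no
new tree.  Finally all MPTs of all analyses are deduplicated, the labelled
nRF distance matrix is assembled, and the congruence-based selection combines
the sk analyses' MPTs with the closest trees of the other batches into a
strict consensus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

from .dependency_model import DependencyGraph, SerialBlock, build_dependency_graph
from .matrix_io import CharacterMatrix, read_tnt_matrix, write_table, write_trees
from .parsimony_scoring import (
    ParsimonyScorer,
    WeightingScheme,
    compute_sk,
)
from .tree_compare import distance_matrix, internal_distance, select_congruent_mpts
from .tree_search import (
    SearchConfig,
    bootstrap_support,
    multistart_search,
    strict_consensus,
    swap_to_local_optimum,
    update_tree_collection,
)
from .trees import PhyloTree, TreeCollection


@dataclass
class DatasetSpec:
    """One matrix to analyse, with or without dependency composites."""

    name: str
    matrix: Union[str, Path, CharacterMatrix]
    use_composites: bool = False
    serial_blocks: Sequence[SerialBlock] = ()

    def load(self) -> Tuple[CharacterMatrix, DependencyGraph]:
        m = (
            self.matrix
            if isinstance(self.matrix, CharacterMatrix)
            else read_tnt_matrix(str(self.matrix))
        )
        graph = build_dependency_graph(m, serial_blocks=self.serial_blocks)
        return m, graph


@dataclass
class PipelineConfig:
    datasets: List[DatasetSpec]
    k_values: Sequence[float] = tuple(range(1, 26))
    ratio_N: float = 15.0
    search_traditional: SearchConfig = field(default_factory=SearchConfig)
    search_composite: SearchConfig = field(
        default_factory=lambda: SearchConfig(
            replicates=5, hits_required=2, ratchet_iterations=0, drift_iterations=0
        )
    )
    bootstrap_traditional: int = 1500
    bootstrap_composite: int = 100
    run_bootstrap: bool = False
    output_dir: Union[str, Path] = "depclad_out"
    seed: int = 0
    max_closure_passes: int = 8

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("at least one dataset required")
        if any(k <= 0 for k in self.k_values):
            raise ValueError("k values must be positive")


def analysis_label(dataset: str, scheme: WeightingScheme, sk: bool = False) -> str:
    """Stable label ``<dataset>:<EW|IWk{k}|IWsk{k}>`` used in filenames,
    manifest entries and distance-matrix rows."""
    if scheme.mode == "EW":
        return f"{dataset}:EW"
    if sk:
        return f"{dataset}:IWsk{scheme.k:.6f}"
    return f"{dataset}:IWk{scheme.k:g}"


def _safe(label: str) -> str:
    return label.replace(":", "_").replace("/", "_")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full protocol; returns (and writes) the run manifest."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "seed": config.seed,
        "ratio_N": config.ratio_N,
        "analyses": [],
        "closure": [],
        "errors": [],
    }

    loaded: Dict[str, Tuple[CharacterMatrix, DependencyGraph]] = {}
    collections: Dict[str, TreeCollection] = {}
    scorers: Dict[str, Dict[str, ParsimonyScorer]] = {}
    batches: Dict[str, List[PhyloTree]] = {}
    sk_labels: List[str] = []

    for ds in config.datasets:
        try:
            matrix, graph = ds.load()
        except Exception as exc:  # recorded, pipeline continues
            manifest["errors"].append({"dataset": ds.name, "error": str(exc)})
            continue
        loaded[ds.name] = (matrix, graph)
        collections[ds.name] = TreeCollection()
        scorers[ds.name] = {}
        search_cfg = (
            config.search_composite if ds.use_composites else config.search_traditional
        )
        base_scorer = ParsimonyScorer(matrix, graph, use_composites=ds.use_composites)

        schemes: List[Tuple[WeightingScheme, bool]] = [(WeightingScheme("EW"), False)]
        schemes += [
            (WeightingScheme("IW", k=float(k), ratio_N=config.ratio_N), False)
            for k in config.k_values
        ]
        ew_trees: List[PhyloTree] = []
        for scheme, is_sk in schemes + [(None, True)]:
            if is_sk:
                try:
                    h_max = base_scorer.max_homoplasy(ew_trees)
                    k_sk = compute_sk(h_max, config.ratio_N)
                except ValueError as exc:
                    manifest["errors"].append(
                        {"dataset": ds.name, "stage": "sk", "error": str(exc)}
                    )
                    continue
                scheme = WeightingScheme("IW", k=k_sk, ratio_N=config.ratio_N)
            label = analysis_label(ds.name, scheme, sk=is_sk)
            seed_i = int(rng.integers(2**31 - 1))
            try:
                scorer = base_scorer.with_scheme(scheme)
                scorers[ds.name][label] = scorer
                result = multistart_search(
                    matrix, graph, scheme,
                    SearchConfig(**{**search_cfg.__dict__, "rng_seed": seed_i}),
                    use_composites=ds.use_composites,
                    scorer=scorer,
                )
                if scheme.mode == "EW":
                    ew_trees = list(result.trees)
                mpt_path = out_dir / f"{_safe(label)}.mpts.nwk"
                write_trees(result.trees, mpt_path)
                cons = strict_consensus(result.trees)
                cons_path = out_dir / f"{_safe(label)}.consensus.nwk"
                cons_path.write_text(cons.to_newick() + "\n")
                record = {
                    "label": label,
                    "dataset": ds.name,
                    "scheme": scheme.mode,
                    "k": scheme.k,
                    "sk": is_sk,
                    "score": float(result.score),
                    "n_mpts": len(result.trees),
                    "seed": seed_i,
                    "mpt_file": str(mpt_path),
                    "consensus_file": str(cons_path),
                }
                if config.run_bootstrap:
                    reps = (
                        config.bootstrap_composite
                        if ds.use_composites
                        else config.bootstrap_traditional
                    )
                    support = bootstrap_support(
                        matrix, graph, scheme, reps, search_cfg,
                        seed=seed_i + 1, use_composites=ds.use_composites,
                    )
                    sup_path = out_dir / f"{_safe(label)}.bootstrap.json"
                    sup_path.write_text(
                        json.dumps(
                            {"|".join(sorted(s)): v for s, v in support.items()},
                            indent=1, sort_keys=True,
                        )
                    )
                    record["bootstrap_file"] = str(sup_path)
                    record["bootstrap_replicates"] = reps
                batches[label] = list(result.trees)
                if is_sk:
                    sk_labels.append(label)
                update_tree_collection(
                    collections[ds.name], result.trees, scorer, label,
                    swap_mode="TBR",
                )
                manifest["analyses"].append(record)
            except Exception as exc:
                manifest["errors"].append(
                    {"dataset": ds.name, "label": label, "error": str(exc)}
                )

    # --- TBR closure loop, with cross-seeding between dataset variants -----
    for pass_no in range(1, config.max_closure_passes + 1):
        added_total = 0
        for name, coll in collections.items():
            # cross-seed: adopt other datasets' trees as TBR start points
            seeds: List[PhyloTree] = []
            leafset = loaded[name][0].taxon_labels
            for other, ocoll in collections.items():
                if other == name:
                    continue
                seeds.extend(
                    t for t in ocoll if t.leaf_set == frozenset(leafset)
                )
            for label, scorer in scorers[name].items():
                best = min(
                    (scorer.total(t) for t in batches.get(label, [])), default=None
                )
                if best is None:
                    continue
                # trees this analysis already holds are local optima under its
                # own scorer; only foreign trees need the TBR cross-check
                have = set(batches[label])
                candidates = []
                for t in list(coll) + seeds:
                    if t not in have and t not in candidates:
                        candidates.append(t)
                for t in candidates:
                    res = swap_to_local_optimum(t, scorer, "TBR")
                    if res.score < best:
                        batches[label] = sorted(
                            res.all_best, key=lambda x: x.to_newick()
                        )
                        best = res.score
                        added_total += coll.update(res.all_best, f"{label}+closure")
                    elif res.score == best:
                        new = [x for x in res.all_best if x not in batches[label]]
                        if new:
                            batches[label] = sorted(
                                set(batches[label]) | set(new),
                                key=lambda x: x.to_newick(),
                            )
                        added_total += coll.update(res.all_best, f"{label}+closure")
        manifest["closure"].append({"pass": pass_no, "added": added_total})
        if added_total == 0:
            break

    manifest["collections"] = {
        name: len(coll) for name, coll in collections.items()
    }

    # --- total comparison ---------------------------------------------------
    leafsets = {frozenset(loaded[n][0].taxon_labels) for n in loaded}
    comparable = len(leafsets) == 1 and batches
    if comparable:
        batch_list = sorted(batches.items())
        dist = distance_matrix(batch_list)
        csv_path = out_dir / "all_mpts_nrf.csv"
        write_table(dist, csv_path, format="csv")
        svg_path = out_dir / "all_mpts_nrf.svg"
        write_table(dist, svg_path, format="svg-heatmap")
        manifest["distance_matrix"] = {
            "n_unique_mpts": len(dist.labels),
            "max_distance": dist.max_distance(),
            "csv": str(csv_path),
            "svg": str(svg_path),
        }
        manifest["internal_distances"] = {
            label: internal_distance(trees) for label, trees in batch_list
        }
        anchors = sk_labels or [batch_list[0][0]]
        try:
            selection = select_congruent_mpts(dict(batch_list), anchors)
            sel_path = out_dir / "congruent_selection.nwk"
            sel_path.write_text(selection.consensus.to_newick() + "\n")
            manifest["congruence_selection"] = {
                "anchors": anchors,
                "n_selected": len(selection.selected),
                "consensus_file": str(sel_path),
                "distances": selection.distances,
            }
        except ValueError as exc:
            manifest["errors"].append({"stage": "selection", "error": str(exc)})

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    manifest["manifest_file"] = str(manifest_path)
    return manifest
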