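"""End-to-end drivers: graph -> trained models -> consolidated partitions."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .datatypes import CellMap, RunConfig, SoftAssignment, SpatialMapSet, TCNPartition
from .ensemble import consensus_partition
from .evaluation import CVResult, run_cv
from .gnn import train_unsupervised
from .graph import SpatialGraph, build_knn_graph, default_k

__all__ = ["unsupervised_tcns", "supervised_tcns"]


def unsupervised_tcns(
    cell_map: CellMap,
    config: RunConfig,
    graph: Optional[SpatialGraph] = None,
) -> tuple[TCNPartition, np.ndarray, SpatialGraph]:
    """Detect TCNs in one map: k-NN graph, n_models runs, majority vote.

    Returns the consolidated partition, the per-cell vote share, and the
    spatial graph used.
    """
    if graph is None:
        k = default_k([cell_map]) if config.k == "auto" else int(config.k)
        graph = build_knn_graph(cell_map, k)
    results = train_unsupervised(graph, config)
    partition, vote_share = consensus_partition(
        [r.assignment for r in results],
        provenance=[f"seed={r.seed}" for r in results],
    )
    return partition, vote_share, graph


def supervised_tcns(
    dataset: SpatialMapSet,
    config: RunConfig,
    n_repeats: Optional[int] = None,
    graphs: Optional[Sequence[SpatialGraph]] = None,
) -> tuple[list[TCNPartition], CVResult]:
    """Condition-supervised TCNs for a labeled cohort.

    Runs repeated stratified k-fold CV; every trained model contributes
    a soft assignment for every map.  Because all maps share one
    assignment head, TCN columns correspond across maps, so the ensemble
    vote is taken over the cohort-concatenated label vectors to keep one
    label space for the whole cohort.
    """
    cv = run_cv(dataset, config, n_repeats=n_repeats, graphs=graphs)
    sizes = [m.n_cells for m in dataset.maps]
    concat = [
        SoftAssignment(np.vstack([a.S for a in per_map]))
        for per_map in cv.assignment_sets
    ]
    partition, _ = consensus_partition(concat)
    bounds = np.cumsum([0] + sizes)
    parts = [
        TCNPartition(partition.labels[bounds[i] : bounds[i + 1]])
        for i in range(len(sizes))
    ]
    return parts, cv
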