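"""Majority-vote consolidation of repeated soft assignments.

Independently trained models produce arbitrary label numberings, so hard
assignments are first aligned to a reference run by Hungarian matching
on the contingency table, then consolidated per cell by majority vote.
The final neighbourhoods are renumbered by descending size.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .datatypes import SoftAssignment, TCNPartition

__all__ = [
    "hard_assign",
    "align_labels",
    "majority_vote",
    "consensus_partition",
    "jaccard_robustness",
]


def hard_assign(S: SoftAssignment | np.ndarray) -> np.ndarray:
    """Per-cell argmax label; probability ties go to the lowest column."""
    arr = S.S if isinstance(S, SoftAssignment) else np.asarray(S, dtype=float)
    return np.argmax(arr, axis=1).astype(int)


def _match_to_reference(ref: np.ndarray, run: np.ndarray) -> dict[int, int]:
    """Map run labels onto reference labels maximizing total overlap.

    Unmatched run labels (when the run uses more labels than the
    reference) receive fresh indices beyond the reference's range.
    """
    ref_labels = np.unique(ref)
    run_labels = np.unique(run)
    overlap = np.zeros((ref_labels.size, run_labels.size))
    for a, rl in enumerate(ref_labels):
        mask = ref == rl
        for b, cl in enumerate(run_labels):
            overlap[a, b] = np.count_nonzero(mask & (run == cl))
    rows, cols = linear_sum_assignment(-overlap)
    mapping = {int(run_labels[b]): int(ref_labels[a]) for a, b in zip(rows, cols)}
    fresh = int(ref_labels.max()) + 1 if ref_labels.size else 0
    for cl in run_labels:
        if int(cl) not in mapping:
            mapping[int(cl)] = fresh
            fresh += 1
    return mapping


def align_labels(
    runs: Sequence[np.ndarray], reference: int = 0
) -> list[np.ndarray]:
    """Permute each run's labels onto the reference run's numbering."""
    runs = [np.asarray(r, dtype=int) for r in runs]
    n = runs[reference].size
    if any(r.size != n for r in runs):
        raise ValueError("all label vectors must have equal length")
    ref = runs[reference]
    aligned = []
    for i, run in enumerate(runs):
        if i == reference:
            aligned.append(run.copy())
            continue
        mapping = _match_to_reference(ref, run)
        aligned.append(np.array([mapping[int(v)] for v in run], dtype=int))
    return aligned


def majority_vote(
    aligned_runs: Sequence[np.ndarray],
    soft: Optional[Sequence[np.ndarray]] = None,
    provenance: Optional[list[str]] = None,
) -> TCNPartition:
    """Per-cell modal label over aligned runs.

    Vote ties prefer the label with the larger summed soft probability
    across runs when ``soft`` (label-aligned probability matrices) is
    given, else the lowest label.  Empty neighbourhoods are dropped and
    the survivors renumbered by descending size.
    """
    runs = np.stack([np.asarray(r, dtype=int) for r in aligned_runs])
    n_runs, n = runs.shape
    n_labels = int(runs.max()) + 1
    votes = np.zeros((n, n_labels), dtype=int)
    for r in runs:
        votes[np.arange(n), r] += 1
    best = votes.max(axis=1)
    labels = np.empty(n, dtype=int)
    for i in range(n):
        tied = np.flatnonzero(votes[i] == best[i])
        if tied.size == 1 or soft is None:
            labels[i] = tied[0]
        else:
            mass = np.zeros(tied.size)
            for S in soft:
                S = np.asarray(S)
                inside = tied < S.shape[1]
                mass[inside] += S[i, tied[inside]]
            labels[i] = tied[int(np.argmax(mass))]
    part = TCNPartition(labels, provenance=provenance or [])
    return part.relabeled_by_size()


def consensus_partition(
    assignments: Sequence[SoftAssignment], provenance: Optional[list[str]] = None
) -> tuple[TCNPartition, np.ndarray]:
    """Full ensemble pipeline: hard assign, align, vote.

    Returns the consolidated partition and the per-cell vote share (the
    fraction of runs agreeing with the winning label, for QC).
    """
    hard = [hard_assign(S) for S in assignments]
    aligned = align_labels(hard, reference=0)
    # align soft matrices by permuting columns with the same mapping
    soft_aligned = []
    for orig, al, S in zip(hard, aligned, (a.S for a in assignments)):
        c = S.shape[1]
        width = max(int(max((a.max() for a in aligned), default=0)) + 1, c)
        P = np.zeros((c, width))
        mapping = {}
        for o, a in zip(orig, al):
            mapping[int(o)] = int(a)
        for col in range(c):
            P[col, mapping.get(col, col)] = 1.0
        soft_aligned.append(S @ P)
    part = majority_vote(aligned, soft=soft_aligned, provenance=provenance)
    stacked = np.stack(aligned)
    modal = np.apply_along_axis(lambda col: np.bincount(col).max(), 0, stacked)
    vote_share = modal / stacked.shape[0]
    return part, vote_share


def _pair_jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Size-weighted mean Jaccard of matched clusters between two partitions."""
    b_aligned = align_labels([a, b], reference=0)[1]
    labels_a = np.unique(a)
    total_w = 0.0
    acc = 0.0
    for la in labels_a:
        set_a = a == la
        set_b = b_aligned == la
        inter = np.count_nonzero(set_a & set_b)
        union = np.count_nonzero(set_a | set_b)
        w = float(np.count_nonzero(set_a))
        acc += w * (inter / union if union else 0.0)
        total_w += w
    return acc / total_w


def jaccard_robustness(partitions: Sequence[TCNPartition | np.ndarray]) -> float:
    """Mean pairwise (size-weighted) Jaccard agreement of TCN partitions."""
    labels = [p.labels if isinstance(p, TCNPartition) else np.asarray(p, dtype=int)
              for p in partitions]
    if len(labels) < 2:
        raise ValueError("need at least two partitions")
    n = labels[0].size
    if any(l.size != n for l in labels):
        raise ValueError("partitions cover different numbers of cells")
    scores = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            # symmetrize: matching is anchored on the first of the pair
            scores.append(0.5 * (_pair_jaccard(labels[i], labels[j])
                                 + _pair_jaccard(labels[j], labels[i])))
    return float(np.mean(scores))
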