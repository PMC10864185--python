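"""Agreement metrics against ground truth and the cross-validated AUC harness.

Macro-F1 matches predicted neighbourhoods one-to-one to ground-truth
classes (Hungarian, maximizing total F1) and averages per-class F1 over
all ground-truth classes, counting unmatched classes as F1 = 0.
Adjusted mutual information uses the arithmetic-mean normalization with
the exact permutation-model (hypergeometric) expected mutual
information.  AUC is the rank-based Mann-Whitney statistic with midrank
tie handling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln
from scipy.stats import rankdata

from .datatypes import RunConfig, SpatialMapSet
from .gnn import SupervisedResult, train_supervised
from .graph import SpatialGraph, build_knn_graph, default_k

__all__ = ["MetricReport", "CVResult", "macro_f1", "ami", "auc", "run_cv"]


@dataclass
class MetricReport:
    macro_f1: float
    per_class_f1: dict[int, float]
    matching: dict[int, int]  # predicted TCN -> GT class


def _contingency(gt: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    gt_labels, gt_idx = np.unique(gt, return_inverse=True)
    pr_labels, pr_idx = np.unique(pred, return_inverse=True)
    table = np.zeros((gt_labels.size, pr_labels.size), dtype=np.int64)
    np.add.at(table, (gt_idx, pr_idx), 1)
    return table, gt_labels, pr_labels


def macro_f1(gt_labels: Sequence[int], pred_labels: Sequence[int]) -> MetricReport:
    """Macro-averaged F1 after one-to-one matching of predictions to classes.

    Cells in unmatched predicted neighbourhoods count as false negatives
    for their ground-truth class; ground-truth classes with no matched
    prediction contribute F1 = 0 to the macro average.
    """
    gt = np.asarray(gt_labels)
    pred = np.asarray(pred_labels)
    if gt.size != pred.size:
        raise ValueError("label vectors differ in length")
    table, gts, prs = _contingency(gt, pred)
    gt_sizes = table.sum(axis=1)
    pr_sizes = table.sum(axis=0)
    # pairwise F1 of (gt class g, predicted cluster p) as a binary problem
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = 2.0 * table / (gt_sizes[:, None] + pr_sizes[None, :])
    f1 = np.nan_to_num(f1)
    rows, cols = linear_sum_assignment(-f1)
    matching = {int(prs[c]): int(gts[r]) for r, c in zip(rows, cols)}
    per_class = {int(g): 0.0 for g in gts}
    for r, c in zip(rows, cols):
        per_class[int(gts[r])] = float(f1[r, c])
    score = float(np.mean(list(per_class.values())))
    return MetricReport(macro_f1=score, per_class_f1=per_class, matching=matching)


def _expected_mi(a: np.ndarray, b: np.ndarray, n: int) -> float:
    """Exact expected mutual information under the permutation model (nats)."""
    emi = 0.0
    log_n = np.log(n)
    gln_n = gammaln(n + 1)
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1)
            term1 = nij / n * (np.log(nij) + log_n - np.log(ai) - np.log(bj))
            log_p = (
                gammaln(ai + 1)
                + gammaln(bj + 1)
                + gammaln(n - ai + 1)
                + gammaln(n - bj + 1)
                - gln_n
                - gammaln(nij + 1)
                - gammaln(ai - nij + 1)
                - gammaln(bj - nij + 1)
                - gammaln(n - ai - bj + nij + 1)
            )
            emi += float(np.sum(term1 * np.exp(log_p)))
    return emi


def ami(gt_labels: Sequence[int], pred_labels: Sequence[int]) -> float:
    """Adjusted mutual information with arithmetic-mean normalization.

    Returns 1 for identical non-constant partitions and 0 when either
    side is a single cluster (the 0/0 limit, by convention).
    """
    gt = np.asarray(gt_labels)
    pred = np.asarray(pred_labels)
    if gt.size != pred.size:
        raise ValueError("label vectors differ in length")
    n = gt.size
    table, _, _ = _contingency(gt, pred)
    if table.shape[0] == 1 or table.shape[1] == 1:
        return 0.0  # a constant side carries no information; 0/0 limit
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    nz = table > 0
    pij = table[nz] / n
    mi = float(np.sum(pij * (np.log(table[nz] * n) - np.log(a[:, None] * b[None, :])[nz])))
    h_gt = float(-np.sum(a / n * np.log(a / n)))
    h_pr = float(-np.sum(b / n * np.log(b / n)))
    emi = _expected_mi(a, b, n)
    denom = 0.5 * (h_gt + h_pr) - emi
    if abs(denom) < 1e-12:
        return 0.0
    return float((mi - emi) / denom)


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.size != s.size:
        raise ValueError("labels and scores differ in length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class CVResult:
    """Repeated stratified k-fold CV output for supervised classification."""

    repeats: list[SupervisedResult]
    per_repeat_auc: list[float]
    mean_auc: float

    @property
    def assignment_sets(self):
        """All per-model (repeats x folds) lists of per-map soft assignments."""
        out = []
        for rep in self.repeats:
            out.extend(rep.assignment_sets)
        return out


def run_cv(
    dataset: SpatialMapSet,
    config: RunConfig,
    n_repeats: Optional[int] = None,
    graphs: Optional[Sequence[SpatialGraph]] = None,
) -> CVResult:
    """Repeated stratified k-fold cross-validation of the supervised model.

    Each repeat reshuffles the stratified fold assignment with a fresh
    seed, trains one model per fold, and scores the pooled held-out
    class probabilities with the rank-based AUC.
    """
    if n_repeats is None:
        n_repeats = config.n_repeats
    if graphs is None:
        k = default_k(dataset) if config.k == "auto" else int(config.k)
        graphs = [build_knn_graph(m, k) for m in dataset.maps]
    repeat_seeds = np.random.SeedSequence(config.seed).generate_state(n_repeats) % (2**31)
    repeats: list[SupervisedResult] = []
    per_auc: list[float] = []
    for seed in repeat_seeds:
        res = train_supervised(dataset, config, graphs=graphs, fold_seed=int(seed))
        if np.any(np.isnan(res.held_out_probs)):
            warnings.warn("missing held-out predictions in a repeat")
        per_auc.append(auc(res.labels, res.held_out_probs[:, 1]))
        repeats.append(res)
    return CVResult(repeats=repeats, per_repeat_auc=per_auc, mean_auc=float(np.mean(per_auc)))
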