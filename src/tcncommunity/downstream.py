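"""Biology-facing statistics on final TCN partitions.

Cell-type enrichment per neighbourhood is a one-sided hypergeometric
over-representation test (observed-or-more cells of a type in the TCN,
drawn from the map), Benjamini-Hochberg adjusted across all
TCN x cell-type tests within one map, reported as -log10(adjusted p).
Within-TCN association of two cell types across samples uses the
Spearman rank correlation; between-TCN communication uses canonical
correlation analysis of each TCN pair's five most enriched cell types
with a permutation test on Wilks' lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import hypergeom, spearmanr
from statsmodels.stats.multitest import multipletests

from .datatypes import CellMap, TCNPartition

__all__ = [
    "EnrichmentMatrix",
    "CCAResult",
    "enrichment_scores",
    "group_average_enrichment",
    "within_tcn_association",
    "between_tcn_cca",
]


@dataclass
class EnrichmentMatrix:
    """TCN x cell-type enrichment scores (-log10 BH-adjusted p) plus counts."""

    scores: pd.DataFrame  # rows: TCN labels; columns: cell types
    raw_p: pd.DataFrame
    counts: pd.DataFrame  # cells of each type per TCN
    tcn_sizes: pd.Series
    type_totals: pd.Series
    n_cells: int


def enrichment_scores(partition: TCNPartition, cell_map: CellMap) -> EnrichmentMatrix:
    """Hypergeometric over-representation of every cell type in every TCN.

    For a TCN of size n_t containing x cells of a type with K copies in
    an N-cell map, p = P(X >= x) for X ~ Hypergeom(N, K, n_t); BH
    adjustment spans all TCN x type tests of this one map.
    """
    if partition.n_cells != cell_map.n_cells:
        raise ValueError("partition does not cover the map")
    vocab = cell_map.vocabulary
    types = np.asarray([vocab.index(t) for t in cell_map.cell_types])
    tcn_labels = np.unique(partition.labels)  # empty TCNs are absent by construction
    N = cell_map.n_cells
    K = np.bincount(types, minlength=len(vocab))
    counts = np.zeros((tcn_labels.size, len(vocab)), dtype=int)
    sizes = np.zeros(tcn_labels.size, dtype=int)
    for r, t in enumerate(tcn_labels):
        mask = partition.labels == t
        sizes[r] = int(mask.sum())
        counts[r] = np.bincount(types[mask], minlength=len(vocab))
    # one-sided upper tail: P(X >= x) = sf(x - 1)
    raw = hypergeom.sf(counts - 1, N, K[None, :], sizes[:, None])
    raw = np.clip(raw, 0.0, 1.0)
    adj = multipletests(raw.ravel(), method="fdr_bh")[1].reshape(raw.shape)
    scores = -np.log10(np.maximum(adj, 1e-300))
    scores[adj >= 1.0] = 0.0
    idx = pd.Index(tcn_labels, name="tcn")
    return EnrichmentMatrix(
        scores=pd.DataFrame(scores, index=idx, columns=vocab),
        raw_p=pd.DataFrame(raw, index=idx, columns=vocab),
        counts=pd.DataFrame(counts, index=idx, columns=vocab),
        tcn_sizes=pd.Series(sizes, index=idx),
        type_totals=pd.Series(K, index=vocab),
        n_cells=N,
    )


def group_average_enrichment(
    matrices: Sequence[EnrichmentMatrix | pd.DataFrame],
    condition_labels: Sequence[int],
) -> dict[int, pd.DataFrame]:
    """Elementwise mean enrichment per condition over maps.

    TCNs absent from a map (empty there) are excluded from that entry's
    mean rather than counted as zero.
    """
    frames = [m.scores if isinstance(m, EnrichmentMatrix) else m for m in matrices]
    if len(frames) != len(condition_labels):
        raise ValueError("one condition label per map is required")
    out: dict[int, pd.DataFrame] = {}
    for cond in sorted(set(condition_labels)):
        group = [f for f, c in zip(frames, condition_labels) if c == cond]
        if not group:
            raise ValueError(f"no maps in condition {cond}")
        all_tcns = sorted(set().union(*(set(f.index) for f in group)))
        all_types = list(group[0].columns)
        stacked = np.stack(
            [f.reindex(index=all_tcns, columns=all_types).to_numpy() for f in group]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            mean = np.nanmean(stacked, axis=0)
        out[cond] = pd.DataFrame(mean, index=pd.Index(all_tcns, name="tcn"), columns=all_types)
    return out


def within_tcn_association(
    matrices: Sequence[EnrichmentMatrix | pd.DataFrame],
    tcn: int,
    type_a: str,
    type_b: str,
) -> tuple[float, float]:
    """Spearman rho (and two-sided p) of two types' enrichment across maps.

    Maps lacking the TCN are skipped; a constant score vector makes the
    correlation undefined and is reported as (nan, nan).
    """
    frames = [m.scores if isinstance(m, EnrichmentMatrix) else m for m in matrices]
    xs, ys = [], []
    for f in frames:
        if tcn in f.index:
            xs.append(float(f.loc[tcn, type_a]))
            ys.append(float(f.loc[tcn, type_b]))
    if len(xs) < 4:
        raise ValueError(f"TCN {tcn} present in only {len(xs)} maps (need >= 4)")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return (float("nan"), float("nan"))
    rho, p = spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class CCAResult:
    tcn_a: int
    tcn_b: int
    correlations: np.ndarray  # non-increasing, in [0, 1]
    p_value: float
    weights_a: np.ndarray  # first canonical variate, scaled to unit max |w|
    weights_b: np.ndarray
    types_a: list[str]
    types_b: list[str]
    n_maps: int


def _drop_collinear(X: np.ndarray, names: list[str], tol: float = 1e-10):
    """Drop columns that add no rank (QR pivot magnitude below tol)."""
    Xc = X - X.mean(axis=0)
    q, r, piv = scipy.linalg.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    scale = diag[0] if diag.size and diag[0] > 0 else 1.0
    keep_pivots = sorted(piv[i] for i in range(len(diag)) if diag[i] > tol * scale)
    if len(keep_pivots) < X.shape[1]:
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep_pivots]
        warnings.warn(f"dropping collinear enrichment columns: {dropped}")
    return X[:, keep_pivots], [names[j] for j in keep_pivots]


def _canonical_correlations(X: np.ndarray, Y: np.ndarray):
    """Classical CCA via QR + SVD; returns correlations and weight matrices."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    qx, rx = np.linalg.qr(Xc)
    qy, ry = np.linalg.qr(Yc)
    u, s, vt = np.linalg.svd(qx.T @ qy)
    r = np.clip(s, 0.0, 1.0)
    k = min(X.shape[1], Y.shape[1])
    wa = scipy.linalg.solve_triangular(rx, u[:, :k])
    wb = scipy.linalg.solve_triangular(ry, vt.T[:, :k])
    return r[:k], wa, wb


def _wilks_lambda(r: np.ndarray) -> float:
    return float(np.prod(1.0 - r**2))


def between_tcn_cca(
    matrices: Sequence[EnrichmentMatrix | pd.DataFrame],
    tcn_a: int,
    tcn_b: int,
    n_perm: int = 999,
    n_vars: int = 5,
    rng: Optional[np.random.Generator] = None,
) -> CCAResult:
    """Canonical correlation between two TCNs' top enriched cell types.

    Observed variables per TCN are its ``n_vars`` most enriched cell
    types by mean score across maps; the permutation p-value permutes
    one side's rows and compares Wilks' lambda over all canonical pairs.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    frames = [m.scores if isinstance(m, EnrichmentMatrix) else m for m in matrices]
    shared = [f for f in frames if tcn_a in f.index and tcn_b in f.index]
    if len(shared) < 6:
        raise ValueError(f"only {len(shared)} maps contain both TCNs (need >= 6)")
    types = list(shared[0].columns)
    mean_a = np.mean([f.loc[tcn_a, types].to_numpy(dtype=float) for f in shared], axis=0)
    mean_b = np.mean([f.loc[tcn_b, types].to_numpy(dtype=float) for f in shared], axis=0)
    take = min(n_vars, len(types))
    top_a = [types[j] for j in np.argsort(-mean_a, kind="stable")[:take]]
    top_b = [types[j] for j in np.argsort(-mean_b, kind="stable")[:take]]
    X = np.stack([f.loc[tcn_a, top_a].to_numpy(dtype=float) for f in shared])
    Y = np.stack([f.loc[tcn_b, top_b].to_numpy(dtype=float) for f in shared])
    X, top_a = _drop_collinear(X, top_a)
    Y, top_b = _drop_collinear(Y, top_b)
    if X.shape[1] < 1 or Y.shape[1] < 1:
        raise ValueError("no usable variables after dropping collinear columns")
    r, wa, wb = _canonical_correlations(X, Y)
    observed = _wilks_lambda(r)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(X.shape[0])
        r_p, _, _ = _canonical_correlations(X[perm], Y)
        if _wilks_lambda(r_p) <= observed:
            count += 1
    p = (1 + count) / (n_perm + 1)
    wa1 = wa[:, 0] / np.max(np.abs(wa[:, 0]))
    wb1 = wb[:, 0] / np.max(np.abs(wb[:, 0]))
    return CCAResult(
        tcn_a=tcn_a,
        tcn_b=tcn_b,
        correlations=r,
        p_value=float(p),
        weights_a=wa1,
        weights_b=wb1,
        types_a=top_a,
        types_b=top_b,
        n_maps=X.shape[0],
    )
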