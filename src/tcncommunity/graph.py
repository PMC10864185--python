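"""k-NN cellular spatial graph construction.

Each cell is connected to its k nearest neighbours by Euclidean
distance; the directed k-NN relation is then symmetrised (edge {i, j}
exists iff j is among i's k nearest OR i is among j's) and self-edges
are dropped.  The adjacency is unweighted {0,1}; node attributes are the
one-hot encoded cell phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .datatypes import CellMap, SpatialMapSet

__all__ = ["SpatialGraph", "default_k", "build_knn_graph", "one_hot"]


@dataclass
class SpatialGraph:
    """Undirected, self-loop-free spatial graph with one-hot attributes.

    ``A`` is the n x n symmetric binary adjacency (CSR), ``F`` the n x m
    one-hot phenotype matrix and ``degrees`` the row sums of ``A``.
    """

    A: sp.csr_matrix
    F: np.ndarray
    k: int

    def __post_init__(self) -> None:
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("adjacency must be square")
        if self.F.shape[0] != n:
            raise ValueError("attribute row count must match graph order")
        if not np.allclose(self.F.sum(axis=1), 1.0):
            raise ValueError("each attribute row must sum to exactly 1")

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.A.sum(axis=1)).ravel()

    @property
    def n_edges(self) -> int:
        return int(self.A.nnz // 2)

    def edge_list(self) -> np.ndarray:
        """Undirected edges as an (E, 2) array of 0-based pairs i < j."""
        coo = sp.triu(self.A, k=1).tocoo()
        edges = np.column_stack([coo.row, coo.col])
        return edges[np.lexsort((edges[:, 1], edges[:, 0]))]


def default_k(dataset: SpatialMapSet | Sequence[CellMap]) -> int:
    """Square-root-of-mean-cells (SRM) rule: one k shared by the dataset.

    Returns round(sqrt(mean(n_i))) with a floor of 1.
    """
    maps = dataset.maps if isinstance(dataset, SpatialMapSet) else list(dataset)
    if not maps:
        raise ValueError("empty dataset")
    mean_n = float(np.mean([m.n_cells for m in maps]))
    return max(1, int(round(np.sqrt(mean_n))))


def _knn_neighbors_exact(coords: np.ndarray, k: int) -> np.ndarray:
    """Tie-exact k-NN: kd-tree candidates widened until the cut is unambiguous."""
    n = coords.shape[0]
    tree = cKDTree(coords)
    out = np.empty((n, k), dtype=np.int64)
    kq = min(k + 2, n)
    dist, idx = tree.query(coords, k=kq)
    if dist.ndim == 1:
        dist, idx = dist[:, None], idx[:, None]
    for i in range(n):
        cand_idx, cand_dist = idx[i], dist[i]
        keep = cand_idx != i
        cand_idx, cand_dist = cand_idx[keep], cand_dist[keep]
        # widen while the (k)-th and (k+1)-th candidate distances tie or
        # the candidate list is too short to certify the cut
        while cand_idx.size < n - 1 and (
            cand_idx.size < k + 1 or cand_dist[k] == cand_dist[k - 1]
        ):
            kq = min(2 * kq, n)
            d2, i2 = tree.query(coords[i], k=kq)
            keep2 = i2 != i
            cand_idx, cand_dist = i2[keep2], d2[keep2]
            if kq == n:
                break
        order = np.lexsort((cand_idx, cand_dist))
        out[i] = cand_idx[order][:k]
    return out


def build_knn_graph(cell_map: CellMap, k: int) -> SpatialGraph:
    """Build the symmetrised k-NN spatial graph for one cell map.

    Distance ties are broken deterministically toward the lower cell
    index.  Duplicated coordinates are allowed (zero-distance
    neighbours); ``k`` must satisfy 1 <= k <= n - 1.
    """
    n = cell_map.n_cells
    if k < 1 or k >= n:
        raise ValueError(f"k must satisfy 1 <= k <= n-1 = {n - 1}, got {k}")
    nbrs = _knn_neighbors_exact(cell_map.coords, k)
    rows = np.repeat(np.arange(n), k)
    cols = nbrs.ravel()
    directed = sp.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n)).tocsr()
    undirected = directed.maximum(directed.T)
    undirected.setdiag(0)
    undirected.eliminate_zeros()
    undirected.data[:] = 1.0
    F = one_hot(cell_map, cell_map.vocabulary)
    return SpatialGraph(A=undirected.tocsr(), F=F, k=k)


def one_hot(cell_map: CellMap, vocabulary: Sequence[str]) -> np.ndarray:
    """One-hot encode cell phenotypes against an ordered vocabulary."""
    index = {t: j for j, t in enumerate(vocabulary)}
    F = np.zeros((cell_map.n_cells, len(vocabulary)))
    for i, t in enumerate(cell_map.cell_types):
        if t not in index:
            raise ValueError(
                f"cell {cell_map.cell_ids[i]!r} has unknown type {t!r}"
            )
        F[i, index[t]] = 1.0
    return F
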