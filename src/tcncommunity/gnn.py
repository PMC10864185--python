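"""Soft TCN assignment model and training loops.

The model maps a node-attributed spatial graph (A, F) to a
row-stochastic soft assignment S of cells to at most c neighbourhoods:

    X = ReLU(F Th1' + (A F) Th2')          one graph-convolution layer
    S = softmax(X Th3')                    linear layer + row softmax

trained with the relaxed normalized-MinCut objective

    L = -tr(S'AS)/tr(S'DS) + || S'S/||S'S||_F - I_c/sqrt(c) ||_F

whose first (cut) term rewards assignments that cut few edges and whose
second (orthogonality) term pushes S toward balanced, unambiguous
clusters.  Supervised mode pools the graph (X_pooled = S'X,
A_pooled = S'AS), applies a second convolution on the coarse graph,
mean-pools to a whole-graph embedding, and classifies the sample with a
two-layer head; the total loss is beta * L_MinCut + (1-beta) * L_CE.

All training runs on a small numpy reverse-mode autodiff tape with Adam.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from . import _autograd as ag
from ._autograd import Tensor
from .datatypes import CellMap, RunConfig, SoftAssignment, SpatialMapSet
from .graph import SpatialGraph, build_knn_graph, default_k

__all__ = [
    "EdgelessGraphError",
    "CoarseGraph",
    "UnsupervisedParams",
    "SupervisedParams",
    "graph_conv",
    "soft_assign",
    "mincut_loss",
    "pool",
    "classify_graph",
    "supervised_loss",
    "train_unsupervised",
    "train_supervised",
    "UnsupervisedModelResult",
    "SupervisedResult",
]


class EdgelessGraphError(ValueError):
    """Raised when the MinCut loss is evaluated on a graph with no edges.

    The cut ratio tr(S'AS)/tr(S'DS) is 0/0 on an edgeless graph; rather
    than silently returning NaN the loss refuses such graphs.
    """


# ---------------------------------------------------------------------------
# parameters


def _glorot(rng: np.random.Generator, out_dim: int, in_dim: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (in_dim + out_dim))
    return rng.uniform(-limit, limit, size=(out_dim, in_dim))


@dataclass
class UnsupervisedParams:
    """Trainable tensors of the unsupervised model (shapes d x m, d x m, c x d)."""

    theta1: Tensor
    theta2: Tensor
    theta3: Tensor

    @classmethod
    def init(cls, m: int, d: int, c: int, rng: np.random.Generator) -> "UnsupervisedParams":
        return cls(
            theta1=ag.parameter(_glorot(rng, d, m)),
            theta2=ag.parameter(_glorot(rng, d, m)),
            theta3=ag.parameter(_glorot(rng, c, d)),
        )

    def tensors(self) -> list[Tensor]:
        return [self.theta1, self.theta2, self.theta3]


@dataclass
class SupervisedParams(UnsupervisedParams):
    """Adds the pooled-graph convolution and two-layer classifier head."""

    theta4: Tensor = None  # d x d, self-transform on the coarse graph
    theta5: Tensor = None  # d x d, neighbour-transform on the coarse graph
    w1: Tensor = None  # h x d
    b1: Tensor = None  # h
    w2: Tensor = None  # 2 x h
    b2: Tensor = None  # 2

    @classmethod
    def init(
        cls, m: int, d: int, c: int, rng: np.random.Generator, hidden: Optional[int] = None
    ) -> "SupervisedParams":
        h = hidden if hidden is not None else max(1, d // 4)
        return cls(
            theta1=ag.parameter(_glorot(rng, d, m)),
            theta2=ag.parameter(_glorot(rng, d, m)),
            theta3=ag.parameter(_glorot(rng, c, d)),
            theta4=ag.parameter(_glorot(rng, d, d)),
            theta5=ag.parameter(_glorot(rng, d, d)),
            w1=ag.parameter(_glorot(rng, h, d)),
            b1=ag.parameter(np.zeros(h)),
            w2=ag.parameter(_glorot(rng, 2, h)),
            b2=ag.parameter(np.zeros(2)),
        )

    def tensors(self) -> list[Tensor]:
        return super().tensors() + [self.theta4, self.theta5, self.w1, self.b1, self.w2, self.b2]


@dataclass
class CoarseGraph:
    """Pooled c-node graph: X_pooled = S'X (c x d), A_pooled = S'AS (c x c)."""

    X_pooled: np.ndarray
    A_pooled: np.ndarray


# ---------------------------------------------------------------------------
# tensor-path building blocks (shared by public ops and training loops)


def _conv_t(F: Tensor, AF: Tensor, theta_self: Tensor, theta_nbr: Tensor) -> Tensor:
    return ag.relu(ag.add(
        ag.matmul(F, ag.transpose(theta_self)),
        ag.matmul(AF, ag.transpose(theta_nbr)),
    ))


def _assign_t(X: Tensor, theta3: Tensor) -> Tensor:
    return ag.row_softmax(ag.matmul(X, ag.transpose(theta3)))


def _mincut_t(S: Tensor, A: sp.spmatrix, degrees: np.ndarray) -> Tensor:
    if A.nnz == 0:
        raise EdgelessGraphError("MinCut loss undefined on a graph with no edges")
    c = S.value.shape[1]
    AS = ag.spmm(A, S, AT=A)  # adjacency is symmetric
    cut_num = ag.tsum(ag.mul(S, AS))
    cut_den = ag.tsum(ag.mul(ag.mul(S, S), ag.constant(degrees[:, None])))
    cut = ag.div(ag.mul(cut_num, ag.constant(-1.0)), cut_den)
    StS = ag.matmul(ag.transpose(S), S)
    target = ag.constant(np.eye(c) / math.sqrt(c))
    ortho = ag.fro_norm(ag.add(
        ag.div(StS, ag.fro_norm(StS)),
        ag.mul(target, ag.constant(-1.0)),
    ))
    return ag.add(cut, ortho)


def _normalize_pooled_adj(Ap: Tensor) -> Tensor:
    """Zero the diagonal and symmetrically degree-normalize S'AS.

    The standard MinCut-pooling operator applies this rescaling to
    the coarse adjacency before the next convolution; without it the
    entries grow like n*k/c and saturate the classifier head.  Fully
    differentiable, with a small epsilon guarding isolated pooled nodes.
    """
    c = Ap.value.shape[0]
    off = ag.mul(Ap, ag.constant(1.0 - np.eye(c)))
    s = ag.sqrt(ag.add(ag.tsum(off, axis=1, keepdims=True), ag.constant(1e-12)))
    return ag.div(ag.div(off, s), ag.transpose(s))


def _classify_logits_t(S: Tensor, X: Tensor, A: sp.spmatrix, params: SupervisedParams) -> Tensor:
    """Pooled graph -> second convolution -> mean -> 2-layer head (logits)."""
    St = ag.transpose(S)
    Xp = ag.matmul(St, X)
    Ap = _normalize_pooled_adj(ag.matmul(St, ag.spmm(A, S, AT=A)))
    Y = ag.relu(ag.add(
        ag.matmul(Xp, ag.transpose(params.theta4)),
        ag.matmul(ag.matmul(Ap, Xp), ag.transpose(params.theta5)),
    ))
    c = S.value.shape[1]
    g = ag.matmul(ag.constant(np.full((1, c), 1.0 / c)), Y)  # 1 x d whole-graph embedding
    h1 = ag.relu(ag.add(ag.matmul(g, ag.transpose(params.w1)), params.b1))
    return ag.add(ag.matmul(h1, ag.transpose(params.w2)), params.b2)


# ---------------------------------------------------------------------------
# public (numpy in / numpy out) operations


def _as_sparse(A) -> sp.csr_matrix:
    return A.tocsr() if sp.issparse(A) else sp.csr_matrix(np.asarray(A, dtype=float))


def graph_conv(
    features: np.ndarray,
    adjacency,
    theta_self: np.ndarray,
    theta_nbr: np.ndarray,
) -> np.ndarray:
    """One graph-convolution layer: ReLU(x_i Th1' + sum_{j in N(i)} x_j Th2')."""
    A = _as_sparse(adjacency)
    X = np.asarray(features, dtype=float)
    if X.shape[0] != A.shape[0]:
        raise ValueError("feature row count must match graph order")
    out = X @ np.asarray(theta_self).T + (A @ X) @ np.asarray(theta_nbr).T
    return np.maximum(out, 0.0)


def soft_assign(X: np.ndarray, theta3: np.ndarray) -> SoftAssignment:
    """Row-softmax of the linear layer X Th3' (max-subtracted for stability)."""
    t = _assign_t(ag.constant(X), ag.constant(theta3))
    return SoftAssignment(t.value)


def mincut_loss(S, A, degrees: Optional[np.ndarray] = None) -> float:
    """Relaxed normalized-MinCut loss of a soft assignment on a graph."""
    S_arr = S.S if isinstance(S, SoftAssignment) else np.asarray(S, dtype=float)
    A_sp = _as_sparse(A)
    if degrees is None:
        degrees = np.asarray(A_sp.sum(axis=1)).ravel()
    return float(_mincut_t(ag.constant(S_arr), A_sp, np.asarray(degrees, dtype=float)).value)


def pool(S, X: np.ndarray, A) -> CoarseGraph:
    """Differentiable pooling: X_pooled = S'X, A_pooled = S'AS."""
    S_arr = S.S if isinstance(S, SoftAssignment) else np.asarray(S, dtype=float)
    A_sp = _as_sparse(A)
    return CoarseGraph(X_pooled=S_arr.T @ np.asarray(X, dtype=float),
                       A_pooled=S_arr.T @ (A_sp @ S_arr))


def classify_graph(coarse: CoarseGraph, params: SupervisedParams) -> np.ndarray:
    """Class probabilities of a pooled graph under the classifier head.

    The pooled adjacency is diagonal-zeroed and symmetrically
    degree-normalized inside the coarse-graph convolution (the standard
    MinCut-pooling convention).
    """
    Xp = ag.constant(coarse.X_pooled)
    Ap = _normalize_pooled_adj(ag.constant(coarse.A_pooled))
    Y = ag.relu(ag.add(
        ag.matmul(Xp, ag.transpose(params.theta4)),
        ag.matmul(ag.matmul(Ap, Xp), ag.transpose(params.theta5)),
    ))
    c = coarse.X_pooled.shape[0]
    g = ag.matmul(ag.constant(np.full((1, c), 1.0 / c)), Y)
    h1 = ag.relu(ag.add(ag.matmul(g, ag.transpose(params.w1)), params.b1))
    logits = ag.add(ag.matmul(h1, ag.transpose(params.w2)), params.b2)
    return ag.row_softmax(logits).value.ravel()


def supervised_loss(
    pred: np.ndarray,
    label: int,
    S,
    A,
    degrees: Optional[np.ndarray] = None,
    beta: float = 0.9,
) -> float:
    """beta * L_MinCut + (1 - beta) * cross-entropy of the class prediction."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    lm = mincut_loss(S, A, degrees)
    p = float(np.asarray(pred).ravel()[int(label)])
    ce = -math.log(max(p, 1e-300))
    return beta * lm + (1.0 - beta) * ce


# ---------------------------------------------------------------------------
# unsupervised training


@dataclass
class UnsupervisedModelResult:
    """One trained model: best-loss soft assignment plus its loss trace."""

    assignment: SoftAssignment
    loss_trace: list[float]
    best_loss: float
    seed: int


def _model_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def train_unsupervised(
    graph: SpatialGraph, config: RunConfig
) -> list[UnsupervisedModelResult]:
    """Train ``config.n_models`` independently seeded models on one graph.

    Each model keeps the soft assignment attaining its lowest observed
    loss.  A model whose loss goes non-finite is aborted with a warning
    and the remaining models continue.
    """
    A = graph.A.astype(np.float32)
    degrees = graph.degrees.astype(np.float32)
    m = graph.F.shape[1]
    results: list[UnsupervisedModelResult] = []
    for seed in _model_seeds(config.seed, config.n_models):
        rng = np.random.default_rng(seed)
        with ag.default_dtype(np.float32):  # training runs in single precision
            F_t = ag.constant(graph.F)
            AF_t = ag.constant(A @ graph.F)
            params = UnsupervisedParams.init(m, config.d, config.c, rng)
        opt = ag.Adam(params.tensors(), lr=config.learning_rate)
        best_loss = math.inf
        best_S: Optional[np.ndarray] = None
        trace: list[float] = []
        stale = 0
        ok = True
        for _ in range(config.max_epochs):
            with ag.default_dtype(np.float32):
                S_t = _assign_t(_conv_t(F_t, AF_t, params.theta1, params.theta2), params.theta3)
                loss_t = _mincut_t(S_t, A, degrees)
            loss = float(loss_t.value)
            if not math.isfinite(loss):
                warnings.warn(f"non-finite loss in model seed {seed}; model aborted")
                ok = False
                break
            trace.append(loss)
            if loss < best_loss - config.min_improvement:
                stale = 0
            else:
                stale += 1
            if loss < best_loss:
                best_loss = loss
                S64 = S_t.value.astype(np.float64)
                best_S = S64 / S64.sum(axis=1, keepdims=True)
            if stale >= config.patience:
                break
            opt.zero_grad()
            with ag.default_dtype(np.float32):
                loss_t.backward()
            opt.step()
        if ok and best_S is not None:
            results.append(
                UnsupervisedModelResult(
                    assignment=SoftAssignment(best_S),
                    loss_trace=trace,
                    best_loss=best_loss,
                    seed=seed,
                )
            )
    if not results:
        raise RuntimeError("all unsupervised models diverged")
    return results


# ---------------------------------------------------------------------------
# supervised training (one set of stratified k-fold cross-validation)


@dataclass
class SupervisedFold:
    fold: int
    test_indices: list[int]
    assignments: list[SoftAssignment]  # forward pass on EVERY map
    test_probs: np.ndarray  # (len(test_indices), 2)
    loss_trace: list[float] = field(default_factory=list)


@dataclass
class SupervisedResult:
    """One set of k-fold CV: per-fold models and pooled held-out predictions."""

    folds: list[SupervisedFold]
    held_out_probs: np.ndarray  # (n_maps, 2)
    labels: np.ndarray
    k: int

    @property
    def assignment_sets(self) -> list[list[SoftAssignment]]:
        """One list of per-map soft assignments per trained model."""
        return [f.assignments for f in self.folds]


def _stratified_folds(
    labels: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Shuffled stratified fold assignment; every map tests exactly once."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    offset = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[(j + offset) % n_folds].append(int(i))
        offset += idx.size % n_folds
    return [np.array(sorted(f), dtype=int) for f in folds]


def _minibatch_size(n_train: int, config: RunConfig) -> int:
    if config.minibatch_size is not None:
        if config.minibatch_size > n_train:
            warnings.warn(
                f"minibatch_size {config.minibatch_size} exceeds training-set "
                f"size {n_train}; clipped"
            )
            return n_train
        return config.minibatch_size
    # power of two closest to half the training-set size
    return int(min(n_train, 2 ** round(math.log2(max(n_train / 2.0, 1.0)))))


def _graph_loss_t(
    graph_data: dict, label: int, params: SupervisedParams, beta: float
) -> Tensor:
    X_t = _conv_t(graph_data["F"], graph_data["AF"], params.theta1, params.theta2)
    S_t = _assign_t(X_t, params.theta3)
    lm = _mincut_t(S_t, graph_data["A"], graph_data["deg"])
    logits = _classify_logits_t(S_t, X_t, graph_data["A"], params)
    ce = ag.cross_entropy_logits(logits, int(label))
    return ag.add(ag.mul(lm, ag.constant(beta)), ag.mul(ce, ag.constant(1.0 - beta)))


def _forward_map(graph_data: dict, params: SupervisedParams) -> tuple[np.ndarray, np.ndarray]:
    X_t = _conv_t(graph_data["F"], graph_data["AF"], params.theta1, params.theta2)
    S_t = _assign_t(X_t, params.theta3)
    logits = _classify_logits_t(S_t, X_t, graph_data["A"], params)
    z = logits.value.ravel()
    e = np.exp(z - z.max())
    return S_t.value, e / e.sum()


def train_supervised(
    dataset: SpatialMapSet,
    config: RunConfig,
    graphs: Optional[Sequence[SpatialGraph]] = None,
    fold_seed: Optional[int] = None,
) -> SupervisedResult:
    """One set of stratified k-fold CV under the joint MinCut + CE loss.

    Trains one model per fold on the training maps (shuffled, so sample
    provenance beyond the class label is never seen), records held-out
    class probabilities for the test fold, and runs a forward pass on
    every map with each trained model so all models contribute soft
    assignments to the downstream ensemble.
    """
    if dataset.labels is None:
        raise ValueError("supervised training requires condition labels")
    labels = np.asarray(dataset.labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("supervised training requires both classes present")
    n_maps = len(dataset)
    n_folds = config.n_folds
    min_class = int(np.bincount(labels).min())
    if min_class < n_folds:
        warnings.warn(
            f"smallest class has {min_class} maps < {n_folds} folds; "
            f"reducing folds to {min_class}"
        )
        n_folds = max(2, min_class)
    if graphs is None:
        k = default_k(dataset) if config.k == "auto" else int(config.k)
        graphs = [build_knn_graph(m, k) for m in dataset.maps]
    else:
        k = graphs[0].k
    with ag.default_dtype(np.float32):  # training runs in single precision
        graph_data = [
            {
                "A": g.A.astype(np.float32),
                "F": ag.constant(g.F),
                "AF": ag.constant(g.A @ g.F),
                "deg": g.degrees.astype(np.float32),
            }
            for g in graphs
        ]
    m = len(dataset.vocabulary)
    master = config.seed if fold_seed is None else fold_seed
    seeds = _model_seeds(master, n_folds + 1)
    fold_rng = np.random.default_rng(seeds[-1])
    folds_idx = _stratified_folds(labels, n_folds, fold_rng)

    folds: list[SupervisedFold] = []
    held_out = np.full((n_maps, 2), np.nan)
    for fold_id, test_idx in enumerate(folds_idx):
        train_idx = np.setdiff1d(np.arange(n_maps), test_idx)
        rng = np.random.default_rng(seeds[fold_id])
        with ag.default_dtype(np.float32):
            params = SupervisedParams.init(m, config.d, config.c, rng)
        batch = _minibatch_size(train_idx.size, config)
        lr = config.resolve_learning_rate(batch)
        opt = ag.Adam(params.tensors(), lr=lr)
        best_loss = math.inf
        best_state: Optional[list[np.ndarray]] = None
        stale = 0
        trace: list[float] = []
        for _ in range(config.max_epochs):
            order = train_idx.copy()
            rng.shuffle(order)
            epoch_loss = 0.0
            finite = True
            for start in range(0, order.size, batch):
                chunk = order[start : start + batch]
                opt.zero_grad()
                batch_loss = 0.0
                for i in chunk:
                    with ag.default_dtype(np.float32):
                        loss_t = _graph_loss_t(graph_data[i], labels[i], params, config.beta)
                        scaled = ag.mul(loss_t, ag.constant(1.0 / chunk.size))
                    if not math.isfinite(float(loss_t.value)):
                        finite = False
                        break
                    with ag.default_dtype(np.float32):
                        scaled.backward()
                    batch_loss += float(loss_t.value) / chunk.size
                if not finite:
                    break
                opt.step()
                epoch_loss += batch_loss * chunk.size / order.size
            if not finite:
                warnings.warn(f"non-finite loss in fold {fold_id}; stopping early")
                break
            trace.append(epoch_loss)
            if epoch_loss < best_loss - config.min_improvement:
                stale = 0
            else:
                stale += 1
            if epoch_loss < best_loss:
                best_loss = epoch_loss
                best_state = [t.value.copy() for t in params.tensors()]
            if stale >= config.patience:
                break
        if best_state is not None:
            for t, v in zip(params.tensors(), best_state):
                t.value = v
        assignments: list[SoftAssignment] = []
        test_probs = np.zeros((test_idx.size, 2))
        for i in range(n_maps):
            with ag.default_dtype(np.float32):
                S_val, probs = _forward_map(graph_data[i], params)
            S64 = S_val.astype(np.float64)
            assignments.append(SoftAssignment(S64 / S64.sum(axis=1, keepdims=True)))
            if i in set(test_idx.tolist()):
                pos = int(np.flatnonzero(test_idx == i)[0])
                test_probs[pos] = probs
                held_out[i] = probs
        folds.append(
            SupervisedFold(
                fold=fold_id,
                test_indices=test_idx.tolist(),
                assignments=assignments,
                test_probs=test_probs,
                loss_trace=trace,
            )
        )
    return SupervisedResult(folds=folds, held_out_probs=held_out, labels=labels, k=k)
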