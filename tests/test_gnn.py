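import numpy as np
import pytest
import scipy.sparse as sp

from conftest import four_cycle, two_triangles
from tcncommunity import (
    CellMap,
    RunConfig,
    SoftAssignment,
    ami,
    build_knn_graph,
    classify_graph,
    graph_conv,
    mincut_loss,
    pool,
    soft_assign,
    supervised_loss,
    train_unsupervised,
)
from tcncommunity.gnn import (
    EdgelessGraphError,
    SupervisedParams,
    UnsupervisedParams,
    _assign_t,
    _conv_t,
    _mincut_t,
)
from tcncommunity import _autograd as ag
from tcncommunity.graph import SpatialGraph


# ---------------------------------------------------------------------- conv
def test_graph_conv_identity_weights_sum_neighbours():
    A = np.array([[0.0, 1.0], [1.0, 0.0]])
    x = np.eye(2)
    out = graph_conv(x, A, np.eye(2), np.eye(2))
    np.testing.assert_allclose(out, [[1, 1], [1, 1]])


def test_graph_conv_isolated_node_and_relu_clip():
    A = np.zeros((1, 1))
    out = graph_conv(np.array([[1.0, 0.0]]), A, -np.eye(2), np.zeros((2, 2)))
    np.testing.assert_allclose(out, [[0.0, 0.0]])  # ReLU clips the negative
    out2 = graph_conv(np.array([[1.0, 0.0]]), A, np.eye(2), np.zeros((2, 2)))
    np.testing.assert_allclose(out2, [[1.0, 0.0]])


def test_graph_conv_shape_mismatch():
    with pytest.raises(ValueError):
        graph_conv(np.eye(3), np.zeros((2, 2)), np.eye(3), np.eye(3))


# -------------------------------------------------------------------- assign
def test_soft_assign_zero_weights_uniform():
    S = soft_assign(np.random.default_rng(0).normal(size=(5, 3)), np.zeros((4, 3)))
    np.testing.assert_allclose(S.S, 0.25)


def test_soft_assign_dominant_logit_and_row_sums():
    theta = np.zeros((3, 2))
    theta[1] = [1000.0, 0.0]
    S = soft_assign(np.array([[1.0, 0.0]]), theta)
    assert S.S[0, 1] == pytest.approx(1.0, abs=1e-12)
    rng = np.random.default_rng(1)
    S2 = soft_assign(rng.normal(size=(20, 8)), rng.normal(size=(5, 8)))
    np.testing.assert_allclose(S2.S.sum(axis=1), 1.0, atol=1e-9)


# -------------------------------------------------------------------- mincut
def test_mincut_two_disconnected_triangles_is_minus_one():
    S = np.zeros((6, 2))
    S[:3, 0] = 1.0
    S[3:, 1] = 1.0
    assert mincut_loss(S, two_triangles()) == pytest.approx(-1.0, abs=1e-9)


def test_mincut_four_cycle_split():
    S = np.zeros((4, 2))
    S[:2, 0] = 1.0
    S[2:, 1] = 1.0
    assert mincut_loss(S, four_cycle()) == pytest.approx(-0.5, abs=1e-9)


def test_mincut_uniform_closed_form():
    S = np.full((4, 2), 0.5)
    expected = -1.0 + np.sqrt(2.0 - np.sqrt(2.0))
    assert mincut_loss(S, four_cycle()) == pytest.approx(expected, abs=1e-9)


def test_mincut_edgeless_graph_raises():
    with pytest.raises(EdgelessGraphError):
        mincut_loss(np.full((3, 2), 0.5), np.zeros((3, 3)))


def test_mincut_term_ranges_on_random_stochastic_S():
    rng = np.random.default_rng(7)
    for _ in range(25):
        n = rng.integers(5, 40)
        c = rng.integers(2, 6)
        A = (rng.uniform(size=(n, n)) < 0.2).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        if A.sum() == 0:
            A[0, 1] = A[1, 0] = 1.0
        S = rng.dirichlet(np.ones(c), size=n)
        D = np.diag(A.sum(axis=1))
        cut = -np.trace(S.T @ A @ S) / np.trace(S.T @ D @ S)
        ortho = mincut_loss(S, A) - cut
        assert -1.0 - 1e-9 <= cut <= 1e-9
        assert -1e-9 <= ortho <= 2.0 + 1e-9


# ---------------------------------------------------------------------- pool
def test_pool_one_hot_selects_and_four_cycle_block_sums():
    A = four_cycle()
    S = np.zeros((4, 2))
    S[:2, 0] = 1.0
    S[2:, 1] = 1.0
    X = np.arange(8.0).reshape(4, 2)
    coarse = pool(S, X, A)
    np.testing.assert_allclose(coarse.X_pooled, [[2, 4], [10, 12]])
    np.testing.assert_allclose(coarse.A_pooled, [[2, 2], [2, 2]])


def test_pool_mass_conservation_random():
    rng = np.random.default_rng(11)
    for _ in range(100):
        n = int(rng.integers(5, 50))
        c = int(rng.integers(2, 7))
        A = (rng.uniform(size=(n, n)) < 0.3).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        S = rng.dirichlet(np.ones(c), size=n)
        coarse = pool(S, rng.normal(size=(n, 3)), A)
        assert coarse.A_pooled.sum() == pytest.approx(A.sum(), abs=1e-9)


# ---------------------------------------------------------------- classifier
def _toy_supervised_params(m=2, d=8, c=3, seed=0):
    return SupervisedParams.init(m, d, c, np.random.default_rng(seed))


def test_classifier_zero_head_gives_half_half():
    params = _toy_supervised_params()
    params.w2.value[:] = 0.0
    params.b2.value[:] = 0.0
    coarse = pool(np.full((4, 3), 1 / 3), np.random.default_rng(0).normal(size=(4, 8)),
                  four_cycle())
    probs = classify_graph(coarse, params)
    np.testing.assert_allclose(probs, [0.5, 0.5], atol=1e-12)


def test_classifier_probabilities_sum_to_one():
    params = _toy_supervised_params(seed=3)
    rng = np.random.default_rng(5)
    coarse = pool(rng.dirichlet(np.ones(3), size=4), rng.normal(size=(4, 8)), four_cycle())
    assert classify_graph(coarse, params).sum() == pytest.approx(1.0, abs=1e-12)


def test_permuting_cells_leaves_classification_unchanged():
    rng = np.random.default_rng(9)
    coords = rng.uniform(size=(60, 2))
    types = rng.choice(["B", "T", "N"], size=60).tolist()
    cm = CellMap(cell_ids=[f"c{i}" for i in range(60)], coords=coords, cell_types=types)
    g = build_knn_graph(cm, 5)
    params = _toy_supervised_params(m=3, d=8, c=3, seed=1)
    perm = rng.permutation(60)
    cm2 = CellMap(cell_ids=[cm.cell_ids[i] for i in perm], coords=coords[perm],
                  cell_types=[types[i] for i in perm])
    g2 = build_knn_graph(cm2, 5)

    def forward(graph):
        X = _conv_t(ag.constant(graph.F), ag.constant(graph.A @ graph.F),
                    params.theta1, params.theta2)
        S = _assign_t(X, params.theta3)
        return S.value, pool(S.value, X.value, graph.A)

    S1, coarse1 = forward(g)
    S2, coarse2 = forward(g2)
    np.testing.assert_allclose(S2, S1[perm], atol=1e-9)  # equivariant rows
    np.testing.assert_allclose(
        classify_graph(coarse2, params), classify_graph(coarse1, params), atol=1e-9
    )


# ------------------------------------------------------------ supervised loss
def test_supervised_loss_limits_and_linearity():
    A = four_cycle()
    S = np.zeros((4, 2))
    S[:2, 0] = 1.0
    S[2:, 1] = 1.0
    lm = mincut_loss(S, A)
    assert supervised_loss([0.3, 0.7], 1, S, A, beta=1.0) == pytest.approx(lm)
    assert supervised_loss([1.0, 0.0], 0, S, A, beta=0.0) == pytest.approx(0.0)
    # beta = 0.9 with components (-0.5, ln 2)
    val = supervised_loss([0.5, 0.5], 0, S, A, beta=0.9)
    assert val == pytest.approx(0.9 * (-0.5) + 0.1 * np.log(2.0), abs=1e-12)


# ---------------------------------------------------------------- gradients
def test_mincut_autodiff_matches_finite_differences():
    """Autodiff gradient of the MinCut loss on a 10-node graph vs central FD."""
    rng = np.random.default_rng(13)
    n, m, d, c = 10, 3, 6, 3
    A = (rng.uniform(size=(n, n)) < 0.4).astype(float)
    A = np.triu(A, 1)
    A = sp.csr_matrix(A + A.T)
    F = np.eye(m)[rng.integers(0, m, size=n)]
    deg = np.asarray(A.sum(axis=1)).ravel()
    params = UnsupervisedParams.init(m, d, c, rng)
    F_t = ag.constant(F)
    AF_t = ag.constant(A @ F)

    def loss_value():
        S = _assign_t(_conv_t(F_t, AF_t, params.theta1, params.theta2), params.theta3)
        return _mincut_t(S, A, deg)

    out = loss_value()
    for t in params.tensors():
        t.grad = None
    out.backward()
    eps = 1e-6
    for tensor in params.tensors():
        flat_idx = [(0, 0), tuple(np.unravel_index(tensor.value.size // 2, tensor.value.shape))]
        for idx in flat_idx:
            old = tensor.value[idx]
            tensor.value[idx] = old + eps
            lp = float(loss_value().value)
            tensor.value[idx] = old - eps
            lm = float(loss_value().value)
            tensor.value[idx] = old
            fd = (lp - lm) / (2 * eps)
            an = tensor.grad[idx]
            assert abs(fd - an) <= 1e-4 * max(abs(fd), abs(an), 1e-8)


# ----------------------------------------------------------------- training
def _clique_graph():
    """Two disconnected 20-cliques as a SpatialGraph."""
    n = 40
    A = np.zeros((n, n))
    A[:20, :20] = 1.0
    A[20:, 20:] = 1.0
    np.fill_diagonal(A, 0.0)
    F = np.zeros((n, 2))
    F[:20, 0] = 1.0
    F[20:, 1] = 1.0
    return SpatialGraph(A=sp.csr_matrix(A), F=F, k=19)


def test_unsupervised_recovers_disconnected_cliques():
    g = _clique_graph()
    components = np.repeat([0, 1], 20)
    cfg = RunConfig(mode="unsupervised", c=2, n_models=5, seed=0)  # default d=128
    results = train_unsupervised(g, cfg)
    assert len(results) == 5
    for r in results:
        labels = np.argmax(r.assignment.S, axis=1)
        assert ami(components, labels) == pytest.approx(1.0)
        # best-so-far trace is non-increasing
        best = np.minimum.accumulate(r.loss_trace)
        assert np.all(np.diff(best) <= 1e-12)


def test_unsupervised_model_count_matches_config():
    g = _clique_graph()
    cfg = RunConfig(mode="unsupervised", c=2, d=8, n_models=3, max_epochs=20, seed=1)
    assert len(train_unsupervised(g, cfg)) == 3
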