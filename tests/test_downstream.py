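import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from tcncommunity import (
    CellMap,
    TCNPartition,
    between_tcn_cca,
    enrichment_scores,
    group_average_enrichment,
    within_tcn_association,
)


def _map_with(types):
    n = len(types)
    rng = np.random.default_rng(0)
    return CellMap(
        cell_ids=[f"c{i}" for i in range(n)],
        coords=rng.uniform(size=(n, 2)),
        cell_types=list(types),
    )


def exact_upper_tail(x, N, K, n) -> float:
    """P(X >= x) for X ~ Hypergeom(N, K, n) by exact rational enumeration."""
    total = Fraction(0)
    for i in range(x, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), math.comb(N, n))
    return float(total)


def test_whole_map_tcn_has_zero_scores():
    cm = _map_with(["A"] * 10 + ["B"] * 10)
    em = enrichment_scores(TCNPartition(np.zeros(20, dtype=int)), cm)
    assert np.all(em.scores.to_numpy() == 0.0)
    assert np.all(em.raw_p.to_numpy() == 1.0)


def test_raw_p_matches_exhaustive_tail_enumeration():
    """All TCN x type raw p-values on small random maps vs rational tail sums."""
    rng = np.random.default_rng(4)
    for trial in range(6):
        n = int(rng.integers(20, 61))
        types = rng.choice(["A", "B", "C"], size=n)
        labels = rng.integers(0, 3, size=n)
        cm = _map_with(types)
        em = enrichment_scores(TCNPartition(labels), cm)
        for t in em.scores.index:
            for ty in cm.vocabulary:
                x = int(em.counts.loc[t, ty])
                expected = exact_upper_tail(
                    x, n, int(em.type_totals[ty]), int(em.tcn_sizes[t])
                )
                assert em.raw_p.loc[t, ty] == pytest.approx(expected, rel=1e-9)


def test_bh_monotone_and_single_test_identity():
    rng = np.random.default_rng(8)
    types = rng.choice(["A", "B", "C", "D"], size=200)
    labels = rng.integers(0, 4, size=200)
    em = enrichment_scores(TCNPartition(labels), _map_with(types))
    raw = em.raw_p.to_numpy().ravel()
    adj = 10.0 ** (-em.scores.to_numpy().ravel())
    order = np.argsort(raw)
    assert np.all(np.diff(adj[order]) >= -1e-12)  # BH preserves raw ordering
    # one TCN x one type: adjusted equals raw
    em1 = enrichment_scores(TCNPartition(np.zeros(20, dtype=int)), _map_with(["A"] * 20))
    assert em1.raw_p.iloc[0, 0] == pytest.approx(1.0)


def test_enrichment_invariant_to_cell_order():
    rng = np.random.default_rng(5)
    types = rng.choice(["A", "B"], size=80)
    labels = rng.integers(0, 2, size=80)
    em1 = enrichment_scores(TCNPartition(labels), _map_with(types))
    perm = rng.permutation(80)
    cm2 = _map_with(types[perm])
    em2 = enrichment_scores(TCNPartition(labels[perm]), cm2)
    pd.testing.assert_frame_equal(em1.scores, em2.scores)


def test_group_average_missing_tcn_rule():
    a = pd.DataFrame([[2.0], [4.0]], index=pd.Index([0, 1], name="tcn"), columns=["A"])
    b = pd.DataFrame([[0.0]], index=pd.Index([0], name="tcn"), columns=["A"])
    out = group_average_enrichment([a, b, a], [0, 0, 1])
    assert out[0].loc[0, "A"] == pytest.approx(1.0)
    assert out[0].loc[1, "A"] == pytest.approx(4.0)  # TCN-1 absent from map b
    pd.testing.assert_frame_equal(out[1], a)
    with pytest.raises(ValueError):
        group_average_enrichment([a, b], [0])  # one label per map required


def _frames_from(xs, ys, tcn=0):
    frames = []
    for x, y in zip(xs, ys):
        frames.append(
            pd.DataFrame([[x, y]], index=pd.Index([tcn], name="tcn"), columns=["A", "B"])
        )
    return frames


def test_spearman_monotone_pairs():
    xs = [1.0, 2.0, 3.0, 4.0, 5.0]
    rho, p = within_tcn_association(_frames_from(xs, [2, 4, 9, 16, 30]), 0, "A", "B")
    assert rho == pytest.approx(1.0)
    rho, _ = within_tcn_association(_frames_from(xs, [30, 16, 9, 4, 2]), 0, "A", "B")
    assert rho == pytest.approx(-1.0)


def test_spearman_constant_is_missing_and_few_maps_error():
    rho, p = within_tcn_association(_frames_from([1, 1, 1, 1], [1, 2, 3, 4]), 0, "A", "B")
    assert math.isnan(rho) and math.isnan(p)
    with pytest.raises(ValueError, match="need >= 4"):
        within_tcn_association(_frames_from([1, 2], [1, 2]), 0, "A", "B")


def _cca_frames(X, Y, types_a=("A", "B"), types_b=("C", "D")):
    """Per-map frames holding TCN 0 (vars types_a) and TCN 1 (vars types_b)."""
    frames = []
    cols = list(dict.fromkeys(list(types_a) + list(types_b)))
    for xrow, yrow in zip(X, Y):
        data = np.zeros((2, len(cols)))
        f = pd.DataFrame(data, index=pd.Index([0, 1], name="tcn"), columns=cols)
        for j, t in enumerate(types_a):
            f.loc[0, t] = xrow[j]
        for j, t in enumerate(types_b):
            f.loc[1, t] = yrow[j]
        frames.append(f)
    return frames


def test_cca_one_variable_equals_abs_pearson():
    rng = np.random.default_rng(3)
    x = rng.normal(size=12)
    y = 0.5 * x + rng.normal(size=12)
    frames = _cca_frames(x[:, None] + 5.0, y[:, None] + 5.0, ("A",), ("C",))
    res = between_tcn_cca(frames, 0, 1, n_perm=49, n_vars=1)
    r = abs(pearsonr(x, y)[0])
    assert res.correlations[0] == pytest.approx(r, abs=1e-10)


def test_cca_identical_sides_all_ones():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(10, 2)) + 3.0
    frames = _cca_frames(X, X, ("A", "B"), ("C", "D"))
    res = between_tcn_cca(frames, 0, 1, n_perm=19, n_vars=2)
    np.testing.assert_allclose(res.correlations, 1.0, atol=1e-8)


def test_cca_invariant_to_affine_rescaling():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(14, 2)) + 4.0
    Y = rng.normal(size=(14, 2)) + 4.0
    res1 = between_tcn_cca(_cca_frames(X, Y), 0, 1, n_perm=9, n_vars=2,
                           rng=np.random.default_rng(0))
    X2 = X * np.array([3.0, 0.5]) + np.array([1.0, -2.0])
    res2 = between_tcn_cca(_cca_frames(X2, Y), 0, 1, n_perm=9, n_vars=2,
                           rng=np.random.default_rng(0))
    np.testing.assert_allclose(res1.correlations, res2.correlations, atol=1e-8)


def test_cca_selects_most_enriched_types():
    rng = np.random.default_rng(11)
    n_maps = 8
    frames = []
    for i in range(n_maps):
        f = pd.DataFrame(
            rng.uniform(size=(2, 4)),
            index=pd.Index([0, 1], name="tcn"),
            columns=["A", "B", "C", "D"],
        )
        f.loc[0, "A"] += 10.0  # dominant in TCN 0
        f.loc[1, "D"] += 10.0  # dominant in TCN 1
        frames.append(f)
    res = between_tcn_cca(frames, 0, 1, n_perm=9, n_vars=2)
    assert res.types_a[0] == "A"
    assert res.types_b[0] == "D"
    assert np.max(np.abs(res.weights_a)) == pytest.approx(1.0)
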