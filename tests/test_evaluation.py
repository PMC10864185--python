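import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_mutual_info_score, roc_auc_score

from tcncommunity import ami, auc, macro_f1


# ----------------------------------------------------------------- macro F1
def brute_force_macro_f1(gt: np.ndarray, pred: np.ndarray) -> float:
    """Enumerate all one-to-one matchings (small label counts only)."""
    gts = np.unique(gt)
    prs = np.unique(pred)

    def f1_pair(g, p):
        tp = np.sum((gt == g) & (pred == p))
        gsz = np.sum(gt == g)
        psz = np.sum(pred == p)
        return 2 * tp / (gsz + psz) if gsz + psz else 0.0

    best = -1.0
    if len(prs) >= len(gts):
        for chosen in itertools.permutations(prs, len(gts)):
            score = np.mean([f1_pair(g, p) for g, p in zip(gts, chosen)])
            best = max(best, score)
    else:
        for chosen in itertools.permutations(gts, len(prs)):
            per_class = {int(g): 0.0 for g in gts}
            for g, p in zip(chosen, prs):
                per_class[int(g)] = f1_pair(g, p)
            best = max(best, float(np.mean(list(per_class.values()))))
    return best


def test_macro_f1_perfect_up_to_relabeling():
    gt = np.repeat([0, 1, 2], 10)
    pred = np.repeat([2, 0, 1], 10)
    assert macro_f1(gt, pred).macro_f1 == pytest.approx(1.0)


def test_macro_f1_single_predicted_tcn_two_balanced_classes():
    gt = np.repeat([0, 1], 10)
    pred = np.zeros(20, dtype=int)
    report = macro_f1(gt, pred)
    assert sorted(report.per_class_f1.values()) == pytest.approx([0.0, 2 / 3])
    assert report.macro_f1 == pytest.approx(1 / 3)


@pytest.mark.parametrize("seed", range(8))
def test_macro_f1_matches_exhaustive_matching(seed):
    rng = np.random.default_rng(seed)
    n = 100
    gt = rng.integers(0, 3, size=n)
    pred = rng.integers(0, 4, size=n)
    assert macro_f1(gt, pred).macro_f1 == pytest.approx(
        brute_force_macro_f1(gt, pred), abs=1e-12
    )


def test_macro_f1_relabel_invariance_and_length_check():
    rng = np.random.default_rng(1)
    gt = rng.integers(0, 3, size=50)
    pred = rng.integers(0, 3, size=50)
    relabeled = (pred + 1) % 3
    assert macro_f1(gt, pred).macro_f1 == pytest.approx(macro_f1(gt, relabeled).macro_f1)
    with pytest.raises(ValueError):
        macro_f1(gt, pred[:-1])


# ---------------------------------------------------------------------- AMI
def test_ami_identical_partitions():
    x = np.repeat([0, 1, 2], 7)
    assert ami(x, x) == pytest.approx(1.0)


def test_ami_single_cluster_convention():
    x = np.zeros(20, dtype=int)
    y = np.repeat([0, 1], 10)
    assert ami(x, y) == 0.0
    assert ami(x, x) == 0.0  # 0/0 limit by convention


@pytest.mark.parametrize("seed", range(10))
def test_ami_matches_reference_implementation(seed):
    rng = np.random.default_rng(seed)
    gt = rng.integers(0, 4, size=30)
    pred = rng.integers(0, 3, size=30)
    expected = adjusted_mutual_info_score(gt, pred, average_method="arithmetic")
    assert ami(gt, pred) == pytest.approx(expected, abs=1e-10)


def test_ami_near_zero_for_independent_partitions():
    rng = np.random.default_rng(2)
    gt = rng.integers(0, 3, size=5000)
    pred = rng.integers(0, 3, size=5000)
    assert abs(ami(gt, pred)) < 0.02


# ---------------------------------------------------------------------- AUC
def pair_counting_auc(labels, scores):
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_separated_and_constant():
    assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == pytest.approx(1.0)
    assert auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == pytest.approx(0.5)


def test_auc_six_point_toy_matches_pair_counting():
    labels = [0, 0, 0, 1, 1, 1]
    scores = [0.1, 0.4, 0.35, 0.4, 0.8, 0.05]
    assert auc(labels, scores) == pytest.approx(pair_counting_auc(labels, scores))


@pytest.mark.parametrize("seed", range(5))
def test_auc_matches_reference_and_complement(seed):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, size=40)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    scores = np.round(rng.uniform(size=40), 1)  # force ties
    assert auc(labels, scores) == pytest.approx(roc_auc_score(labels, scores))
    assert auc(labels, scores) + auc(labels, -scores) == pytest.approx(1.0)


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        auc([1, 1, 1], [0.1, 0.2, 0.3])
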