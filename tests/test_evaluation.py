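"""Metric correctness: overlap coefficients, ROC/AUC, bootstrap, operating points."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wsiscreen.evaluation import (
    bootstrap_ci,
    confusion_matrix,
    dice,
    dice_to_jaccard,
    jaccard,
    jaccard_to_dice,
    operating_points,
    pr_curve,
    roc_auc,
)


# ------------------------------------------------------------ Dice/Jaccard

@pytest.mark.parametrize("a, b, d_exp, j_exp", [
    (np.ones((3, 3), bool), np.ones((3, 3), bool), 1.0, 1.0),
    (np.eye(3, dtype=bool), ~np.eye(3, dtype=bool), 0.0, 0.0),
    # |A|=2, |B|=4, |A∩B|=2 -> Dice 4/6, Jaccard 2/4
    (np.array([1, 1, 0, 0, 0, 0], bool), np.array([1, 1, 1, 1, 0, 0], bool), 2 / 3, 0.5),
    (np.zeros(4, bool), np.zeros(4, bool), 1.0, 1.0),  # empty-empty convention
])
def test_dice_jaccard_pixel_enumeration(a, b, d_exp, j_exp):
    assert dice(a, b) == pytest.approx(d_exp)
    assert jaccard(a, b) == pytest.approx(j_exp)


def test_mask_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


@pytest.mark.parametrize("d, j", [(0.80, 0.67), (0.74, 0.59), (1.0, 1.0), (0.0, 0.0)])
def test_dice_jaccard_conversion_matches_reported_pairs(d, j):
    """The algebraic d/(2-d) relation reproduces the paired overlap values."""
    assert round(dice_to_jaccard(d), 2) == j
    assert jaccard_to_dice(dice_to_jaccard(d)) == pytest.approx(d)


@given(st.floats(min_value=0.0, max_value=1.0))
@settings(deadline=None, max_examples=50)
def test_conversion_roundtrip_identity(d):
    assert jaccard_to_dice(dice_to_jaccard(d)) == pytest.approx(d, abs=1e-12)


def test_jaccard_never_exceeds_dice_and_relation_exact(rng):
    for _ in range(30):
        a = rng.random((8, 8)) > 0.5
        b = rng.random((8, 8)) > 0.5
        d, j = dice(a, b), jaccard(a, b)
        assert j <= d + 1e-12
        assert d == pytest.approx(2 * j / (1 + j))


# ------------------------------------------------------------------- ROC

def _auc_pairs(scores, labels):
    """Brute-force Mann-Whitney: count over all (positive, negative) pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_trivial_cases():
    assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]).auc == pytest.approx(1.0)
    assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]).auc == pytest.approx(0.5)


def test_auc_equals_pair_enumeration_small_sets(rng):
    for _ in range(100):
        n = int(rng.integers(2, 13))
        scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        assert roc_auc(scores, labels).auc == pytest.approx(_auc_pairs(scores, labels))


def test_auc_invariant_under_monotone_transform(rng):
    scores = rng.random(20)
    labels = rng.integers(0, 2, size=20)
    labels[0], labels[1] = 0, 1
    base = roc_auc(scores, labels).auc
    assert roc_auc(np.exp(3 * scores), labels).auc == pytest.approx(base)
    assert roc_auc(scores**3 + 7, labels).auc == pytest.approx(base)


def test_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


def test_roc_sensitivity_monotone(rng):
    scores = rng.random(30)
    labels = rng.integers(0, 2, size=30)
    labels[:2] = [0, 1]
    roc = roc_auc(scores, labels)
    assert (np.diff(roc.sensitivity) >= 0).all()  # thresholds descend -> SE rises


# --------------------------------------------------------------- bootstrap

def test_bootstrap_deterministic_and_degenerate():
    scores = [0.9, 0.95, 0.99, 0.05, 0.1, 0.2]
    labels = [1, 1, 1, 0, 0, 0]
    ci1 = bootstrap_ci(scores, labels, n_boot=200, seed=7)
    ci2 = bootstrap_ci(scores, labels, n_boot=200, seed=7)
    assert ci1 == ci2
    assert ci1 == (1.0, 1.0)  # every resample separates perfectly


def test_bootstrap_interval_brackets_auc(rng):
    neg = rng.normal(0, 1, 60)
    pos = rng.normal(1.0, 1, 60)
    scores = np.concatenate([neg, pos])
    labels = np.array([0] * 60 + [1] * 60)
    lo, hi = bootstrap_ci(scores, labels, n_boot=500, seed=3)
    auc = roc_auc(scores, labels).auc
    assert lo <= auc <= hi
    assert 0.0 <= lo < hi <= 1.0


def test_bootstrap_ci_width_shrinks_with_n(rng):
    widths = []
    for n in (50, 500, 5000):
        neg = rng.normal(0, 1, n)
        pos = rng.normal(1.19, 1, n)
        scores = np.concatenate([neg, pos])
        labels = np.array([0] * n + [1] * n)
        lo, hi = bootstrap_ci(scores, labels, n_boot=300, seed=n)
        widths.append(hi - lo)
    assert widths[0] > widths[1] > widths[2]


# --------------------------------------------------------- operating points

def test_operating_points_perfect_classifier():
    scores = [0.9, 0.8, 0.1, 0.2]
    labels = [1, 1, 0, 0]
    ops = operating_points(roc_auc(scores, labels), scores, labels)
    assert ops.p1 == (1.0, 1.0, 1.0)
    assert ops.p2 == (1.0, 1.0, 1.0)
    assert ops.p3 == (1.0, 1.0, 1.0)


def test_operating_points_match_exhaustive_sweep():
    scores = np.array([0.9, 0.7, 0.6, 0.4, 0.3, 0.1])
    labels = np.array([1, 1, 0, 1, 0, 0])
    ops = operating_points(roc_auc(scores, labels), scores, labels)

    best = {"p1": (-1,) * 3, "p2": (-1,) * 3, "p3": (-1,) * 3}
    for t in np.concatenate(([np.inf], np.unique(scores))):
        pred = (scores >= t).astype(int)
        tp = ((pred == 1) & (labels == 1)).sum()
        tn = ((pred == 0) & (labels == 0)).sum()
        se = tp / labels.sum()
        sp = tn / (labels == 0).sum()
        acc = (tp + tn) / labels.size
        if sp == 1.0 and se > best["p1"][0]:
            best["p1"] = (se, sp, acc)
        if se == 1.0 and sp > best["p2"][1]:
            best["p2"] = (se, sp, acc)
        if acc > best["p3"][2]:
            best["p3"] = (se, sp, acc)
    assert ops.p1 == pytest.approx(best["p1"])
    assert ops.p2 == pytest.approx(best["p2"])
    assert ops.p3 == pytest.approx(best["p3"])


def test_p3_accuracy_tie_prefers_higher_sensitivity():
    # thresholds at 0.8 and 0.4 both give accuracy 0.75; the 0.4 one has higher SE
    scores = np.array([0.9, 0.8, 0.4, 0.1])
    labels = np.array([1, 0, 1, 0])
    ops = operating_points(roc_auc(scores, labels), scores, labels)
    assert ops.p3[0] == 1.0  # sensitivity of the chosen tie
    assert ops.p3_threshold <= 0.4


# ------------------------------------------------------------ PR / confusion

def test_pr_curve_trivial_and_enumerated(rng):
    labels = np.array([1, 0, 1, 0, 0, 1, 0, 0, 1, 0])
    scores = rng.random(10)
    precision, recall = pr_curve(scores, labels)
    # lowest threshold = predict everything positive
    assert recall[-1] == pytest.approx(1.0)
    assert precision[-1] == pytest.approx(labels.mean())
    # hand enumeration at each unique threshold
    for t, p, r in zip(np.unique(scores)[::-1], precision, recall):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        assert p == pytest.approx(tp / (tp + fp))
        assert r == pytest.approx(tp / labels.sum())


def test_confusion_matrix_counts():
    m = confusion_matrix([1, 1, 0, 0], [1, 1, 0, 0])
    assert m[0, 1] == 0 and m[1, 0] == 0 and m.sum() == 4
    m = confusion_matrix([1, 0, 1, 0], [1, 1, 0, 0])
    assert m.tolist() == [[1, 1], [1, 1]]
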