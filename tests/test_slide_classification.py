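"""Slide-level features, the T07 statistic, MRMR ranking and thresholding."""

import numpy as np
import pytest

from wsiscreen.inference import TumorMap
from wsiscreen.slide_classification import (
    classify_slide,
    extract_slide_features,
    mrmr_select,
    t07,
    tune_threshold,
)


def _map_from_values(values, ta=None):
    tpm = np.asarray(values, dtype=float).reshape(1, -1)
    ta = np.ones_like(tpm, bool) if ta is None else np.asarray(ta, bool).reshape(1, -1)
    return TumorMap(tpm=tpm, ta=ta)


# ---------------------------------------------------------------- features

def test_feature_hand_count():
    fv = extract_slide_features(_map_from_values([0.9, 0.8, 0.6, 0.5]))
    assert fv.cumhist[7] == pytest.approx(0.5)   # 2 of 4 pixels >= 0.7
    assert fv.cumhist[0] == pytest.approx(1.0)
    assert fv.mean == pytest.approx(0.7)
    assert fv.tumor_area == 4
    assert fv.variance == pytest.approx(fv.std**2)
    assert (np.diff(fv.cumhist) <= 1e-12).all()  # non-increasing in threshold


def test_features_empty_ta_all_zero():
    fv = extract_slide_features(_map_from_values([0.9, 0.9], ta=[0, 0]))
    assert fv.tumor_area == 0
    assert fv.mean == fv.std == fv.variance == 0.0
    assert (fv.cumhist == 0).all()


def test_features_saturated_map():
    fv = extract_slide_features(_map_from_values([1.0, 1.0, 1.0]))
    assert (fv.cumhist == 1.0).all()
    assert fv.std == pytest.approx(0.0)


# -------------------------------------------------------------------- T07

@pytest.mark.parametrize("values, expected", [
    ([0.9, 0.8, 0.6, 0.5], 0.5),
    ([0.7, 0.75, 0.99], 1.0),
    ([0.69, 0.5], 0.0),
])
def test_t07_enumeration(values, expected):
    assert t07(_map_from_values(values)) == pytest.approx(expected)


def test_t07_empty_ta_convention():
    assert t07(_map_from_values([0.9], ta=[0])) == 0.0


def test_t07_equals_cumhist_bin_seven(rng):
    for _ in range(20):
        tpm = rng.random((6, 6))
        ta = rng.random((6, 6)) > 0.4
        tm = TumorMap(tpm=tpm, ta=ta)
        assert t07(tm) == pytest.approx(extract_slide_features(tm).cumhist[7])


def test_t07_monotone_in_tpm(rng):
    tpm = rng.random((5, 5))
    ta = rng.random((5, 5)) > 0.3
    base = t07(TumorMap(tpm=tpm, ta=ta))
    assert t07(TumorMap(tpm=np.clip(tpm + 0.15, 0, 1), ta=ta)) >= base


def test_t07_scale_invariant(rng):
    tpm = rng.random((4, 4))
    ta = np.ones((4, 4), bool)
    doubled = np.tile(tpm, (2, 1))
    assert t07(TumorMap(tpm=doubled, ta=np.ones_like(doubled, bool))) == pytest.approx(
        t07(TumorMap(tpm=tpm, ta=ta)))


# ------------------------------------------------------------------- MRMR

def test_mrmr_label_copy_ranked_first(rng):
    y = rng.integers(0, 2, size=40)
    x = np.column_stack([rng.random(40), y + 0.01 * rng.random(40), rng.random(40)])
    assert mrmr_select(x, y, k=3)[0] == 1


def test_mrmr_full_k_is_permutation(rng):
    x = rng.random((30, 4))
    y = rng.integers(0, 2, size=30)
    y[:2] = [0, 1]
    ranking = mrmr_select(x, y, k=4)
    assert sorted(ranking) == [0, 1, 2, 3]


def test_mrmr_redundant_copy_demoted(rng):
    """A duplicate of the top feature scores relevance - I(f;f) and drops
    below an independent, moderately informative feature."""
    y = rng.integers(0, 2, size=200)
    strong = y + 0.05 * rng.random(200)
    dup = strong + 1e-6 * rng.random(200)
    weak = y * rng.random(200) + 0.5 * rng.random(200)
    x = np.column_stack([strong, dup, weak])
    ranking = mrmr_select(x, y, k=3)
    assert ranking[0] in (0, 1)
    assert ranking[1] == 2  # the non-redundant feature beats the duplicate


def test_mrmr_validates_input(rng):
    x = rng.random((10, 3))
    with pytest.raises(ValueError):
        mrmr_select(x, np.zeros(10), k=2)  # constant labels
    with pytest.raises(ValueError):
        mrmr_select(x, np.r_[np.zeros(5), np.ones(5)], k=5)  # k > n_features


def _mi_table(a, b):
    """Plug-in mutual information from an explicit contingency table."""
    a_vals, b_vals = np.unique(a), np.unique(b)
    n = len(a)
    mi = 0.0
    for av in a_vals:
        for bv in b_vals:
            pab = ((a == av) & (b == bv)).sum() / n
            if pab > 0:
                pa = (a == av).sum() / n
                pb = (b == bv).sum() / n
                mi += pab * np.log(pab / (pa * pb))
    return mi


def test_mrmr_matches_exhaustive_greedy_oracle(rng):
    """Greedy MID ranking equals an independent recomputation of the
    objective from explicit contingency-table MI estimates."""
    for _ in range(25):
        n, f = int(rng.integers(12, 30)), int(rng.integers(2, 6))
        x = rng.random((n, f))
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            continue
        ranking = mrmr_select(x, y, k=f, bins=3)

        # oracle: same discretization rule, independent MI and greedy loop
        disc = []
        for j in range(f):
            qs = np.quantile(x[:, j], [1 / 3, 2 / 3])
            disc.append(np.digitize(x[:, j], np.unique(qs)))
        rel = [round(_mi_table(d, y), 12) for d in disc]
        sel = [int(np.argmax(rel))]
        rem = [j for j in range(f) if j != sel[0]]
        while rem:
            scores = [round(rel[j] - np.mean([round(_mi_table(disc[j], disc[s]), 12)
                                                     for s in sel]), 12) for j in rem]
            nxt = rem[int(np.argmax(scores))]
            sel.append(nxt)
            rem.remove(nxt)
        assert ranking == sel


# ------------------------------------------------------------- thresholds

def test_classify_slide_boundary_rule():
    assert classify_slide(0.5, 0.5) == "cancer"   # inclusive >=
    assert classify_slide(0.0, 0.01) == "normal"


def test_threshold_sweep_reaches_every_confusion_matrix():
    scores = np.array([0.9, 0.7, 0.5, 0.3, 0.2, 0.1])
    labels = np.array([1, 1, 0, 1, 0, 0])
    seen = set()
    for t in np.concatenate(([1.1], np.unique(scores))):
        pred = tuple((scores >= t).astype(int))
        seen.add(pred)
    assert len(seen) == len(np.unique(scores)) + 1  # all distinct predictions


def test_tune_threshold_separated_midpoint():
    scores = [0.1, 0.2, 0.8, 0.9]
    labels = [0, 0, 1, 1]
    assert tune_threshold(scores, labels) == pytest.approx(0.5)


def test_tune_threshold_screening_rule():
    scores = [0.1, 0.45, 0.4, 0.9]
    labels = [0, 0, 1, 1]
    t = tune_threshold(scores, labels, criterion="sensitivity-1")
    assert t == pytest.approx(0.4)
    assert all(s >= t for s, l in zip(scores, labels) if l == 1)


def test_tune_threshold_matches_brute_force():
    scores = np.array([0.05, 0.3, 0.35, 0.6, 0.62, 0.9])
    labels = np.array([0, 0, 1, 0, 1, 1])
    t = tune_threshold(scores, labels)
    acc = ((scores >= t).astype(int) == labels).mean()
    best = max(((scores >= c).astype(int) == labels).mean()
               for c in np.linspace(0, 1, 1001))
    assert acc == pytest.approx(best)
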