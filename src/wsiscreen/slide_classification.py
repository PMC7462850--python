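"""Slide-level scoring from tumor maps.

The whole-slide decision statistic is T07: among the pixels where the
cancer class wins the per-pixel argmax (the tumor area, TA), the fraction
whose tumor probability (TPM) is at least 0.7.  The full feature vector --
a 10-bin cumulative histogram of TPM over TA, the TA pixel count, and
first-order statistics -- feeds a greedy minimum-redundancy
maximum-relevance (MRMR) ranking that, on the kind of cohorts this package
models, puts the 0.7 histogram bin (= T07) at or near the top.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import mutual_info_score

__all__ = [
    "SlideFeatureVector",
    "SlideScore",
    "FEATURE_NAMES",
    "extract_slide_features",
    "t07",
    "mrmr_select",
    "classify_slide",
    "tune_threshold",
]

CUMHIST_THRESHOLDS = np.arange(10) / 10.0  # 0.0, 0.1, ..., 0.9

FEATURE_NAMES = tuple(f"cumhist_{t:.1f}" for t in CUMHIST_THRESHOLDS) + (
    "tumor_area",
    "mean",
    "std",
    "variance",
)


@dataclass
class SlideFeatureVector:
    cumhist: np.ndarray  # fraction of TA pixels with TPM >= t, t = 0.0..0.9
    tumor_area: int
    mean: float
    std: float
    variance: float
    slide_id: str | None = None

    def as_array(self) -> np.ndarray:
        return np.concatenate(
            [self.cumhist, [self.tumor_area, self.mean, self.std, self.variance]]
        )


@dataclass
class SlideScore:
    t07: float
    label: str | None = None
    slide_id: str | None = None


def _ta_values(tumor_map) -> np.ndarray:
    tpm = np.asarray(tumor_map.tpm, dtype=float)
    ta = np.asarray(tumor_map.ta, dtype=bool)
    if tpm.shape != ta.shape:
        raise ValueError("TPM and TA shape mismatch")
    return tpm[ta]


def extract_slide_features(tumor_map, slide_id: str | None = None) -> SlideFeatureVector:
    """Feature vector over the tumor-argmax area; all-zero when TA is empty."""
    vals = _ta_values(tumor_map)
    if vals.size == 0:
        return SlideFeatureVector(
            cumhist=np.zeros(10), tumor_area=0, mean=0.0, std=0.0, variance=0.0,
            slide_id=slide_id,
        )
    cumhist = np.array([(vals >= t).mean() for t in CUMHIST_THRESHOLDS])
    return SlideFeatureVector(
        cumhist=cumhist,
        tumor_area=int(vals.size),
        mean=float(vals.mean()),
        std=float(vals.std()),
        variance=float(vals.var()),
        slide_id=slide_id,
    )


def t07(tumor_map) -> float:
    """T07 = #{TA pixels with TPM >= 0.7} / #TA; 0.0 for an empty TA."""
    vals = _ta_values(tumor_map)
    if vals.size == 0:
        return 0.0
    return float((vals >= 0.7).mean())


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency binning; constant features collapse to a single bin."""
    qs = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.digitize(x, np.unique(qs))


def mrmr_select(features: np.ndarray, labels, k: int, bins: int = 3) -> list[int]:
    """Greedy MRMR ranking (MID scheme: relevance minus mean redundancy).

    The first feature maximizes I(f; y); each next feature maximizes
    I(f; y) - mean_{s in selected} I(f; f_s).  Mutual information is the
    plug-in estimate on equal-frequency discretized features, rounded to
    12 decimals so exact ties break toward the lower feature index
    regardless of floating-point summation order.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("features must be (n_slides, n_features) matching labels")
    if np.unique(y).size < 2:
        raise ValueError("labels are constant")
    n_feat = x.shape[1]
    if not 1 <= k <= n_feat:
        raise ValueError("k out of range")

    disc = [_discretize(x[:, j], bins) for j in range(n_feat)]
    relevance = np.round([mutual_info_score(d, y) for d in disc], 12)

    selected: list[int] = [int(np.argmax(relevance))]
    remaining = [j for j in range(n_feat) if j != selected[0]]
    red_cache: dict[tuple[int, int], float] = {}

    def _red(a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        if key not in red_cache:
            red_cache[key] = round(mutual_info_score(disc[a], disc[b]), 12)
        return red_cache[key]

    while remaining and len(selected) < k:
        scores = np.round(
            [relevance[j] - np.mean([_red(j, s) for s in selected]) for j in remaining], 12
        )
        best = remaining[int(np.argmax(scores))]
        selected.append(best)
        remaining.remove(best)
    return selected


def classify_slide(score: SlideScore | float, threshold: float) -> str:
    """Label 'cancer' iff t07 >= threshold (inclusive boundary)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    value = score.t07 if isinstance(score, SlideScore) else float(score)
    return "cancer" if value >= threshold else "normal"


def tune_threshold(scores, labels, criterion: str = "accuracy") -> float:
    """Pick the decision threshold on a tuning set.

    criterion='accuracy': threshold maximizing plain accuracy; for perfectly
    separated scores the midpoint of the separating gap is returned.
    criterion='sensitivity-1': the smallest candidate threshold keeping
    sensitivity at 1 (screening rule).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("both classes required to tune a threshold")

    if criterion == "sensitivity-1":
        return float(scores[labels == 1].min())
    if criterion != "accuracy":
        raise ValueError(f"unknown criterion {criterion!r}")

    # candidates: midpoints between adjacent unique scores plus the extremes
    uniq = np.unique(scores)
    cands = np.concatenate(([uniq[0]], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1e-9]))
    accs = [((scores >= t).astype(int) == labels).mean() for t in cands]
    best = np.max(accs)
    # among ties prefer the lowest threshold (higher sensitivity)
    return float(cands[int(np.argmax(accs))]) if accs.count(best) == 1 else float(
        cands[np.flatnonzero(np.asarray(accs) == best)[0]]
    )
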