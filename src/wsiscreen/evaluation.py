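"""Patch- and slide-level evaluation metrics.

Dice/Jaccard overlap for segmentation masks, ROC analysis with trapezoidal
AUC (equal to the Mann-Whitney pair statistic), percentile-bootstrap
confidence intervals over prediction indices, the P1/P2/P3 operating
points (specificity 1, sensitivity 1, best accuracy), precision-recall
curves and confusion matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RocResult",
    "OperatingPoints",
    "dice",
    "jaccard",
    "dice_to_jaccard",
    "jaccard_to_dice",
    "roc_auc",
    "bootstrap_ci",
    "operating_points",
    "pr_curve",
    "confusion_matrix",
]


# ------------------------------------------------------------ mask overlap

def _check_masks(pred, ref):
    pred = np.asarray(pred, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    if pred.shape != ref.shape:
        raise ValueError(f"mask shape mismatch: {pred.shape} vs {ref.shape}")
    return pred, ref


def dice(pred_mask, ref_mask) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    a, b = _check_masks(pred_mask, ref_mask)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def jaccard(pred_mask, ref_mask) -> float:
    """Jaccard index |A∩B|/|A∪B|; 1.0 when both masks are empty."""
    a, b = _check_masks(pred_mask, ref_mask)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def dice_to_jaccard(d: float) -> float:
    """j = d / (2 - d), the exact algebraic relation between the overlaps."""
    d = float(d)
    if not 0.0 <= d <= 1.0:
        raise ValueError("Dice coefficient must be in [0, 1]")
    return d / (2.0 - d)


def jaccard_to_dice(j: float) -> float:
    """d = 2j / (1 + j), the inverse of :func:`dice_to_jaccard`."""
    j = float(j)
    if not 0.0 <= j <= 1.0:
        raise ValueError("Jaccard index must be in [0, 1]")
    return 2.0 * j / (1.0 + j)


# ------------------------------------------------------------- ROC / AUC

@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int | None = None
    seed: int | None = None


@dataclass
class OperatingPoints:
    """SE/SP/ACC triples at specificity 1 (P1), sensitivity 1 (P2), best accuracy (P3)."""

    p1: tuple[float, float, float]
    p2: tuple[float, float, float]
    p3: tuple[float, float, float]
    p3_threshold: float = field(default=np.nan)


def _check_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and of equal length")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return scores, labels


def roc_auc(scores, labels) -> RocResult:
    """ROC over all unique score thresholds (classifier rule: score >= t).

    The trapezoidal area equals the Mann-Whitney statistic
    P(score_pos > score_neg) + 0.5 P(tie) exactly.
    """
    scores, labels = _check_scores(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    # sweep thresholds from +inf down over unique scores
    uniq = np.unique(scores)[::-1]
    thresholds = np.concatenate(([np.inf], uniq))
    tp = np.array([(scores[labels == 1] >= t).sum() for t in thresholds], dtype=float)
    fp = np.array([(scores[labels == 0] >= t).sum() for t in thresholds], dtype=float)
    se = tp / n_pos
    sp = 1.0 - fp / n_neg
    fpr = fp / n_neg
    auc = float(np.trapezoid(se, fpr))
    return RocResult(thresholds=thresholds, sensitivity=se, specificity=sp, auc=auc)


def _auc_only(scores, labels) -> float:
    """Rank-based Mann-Whitney AUC (midranks for ties); fast scalar path."""
    from scipy.stats import rankdata

    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def bootstrap_ci(scores, labels, n_boot: int = 2000, alpha: float = 0.05,
                 seed: int | None = None) -> tuple[float, float]:
    """Percentile bootstrap CI for AUC, resampling prediction indices.

    Resamples that lose one class entirely are redrawn so every bootstrap
    replicate has a defined AUC.
    """
    from scipy.stats import rankdata

    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    scores, labels = _check_scores(scores, labels)
    rng = np.random.default_rng(seed)
    n = scores.size
    idx = rng.integers(0, n, size=(n_boot, n))
    while True:  # redraw resamples that lost one class entirely
        n_pos = labels[idx].sum(axis=1)
        bad = np.flatnonzero((n_pos == 0) | (n_pos == n))
        if bad.size == 0:
            break
        idx[bad] = rng.integers(0, n, size=(bad.size, n))
    s = scores[idx]
    lb = labels[idx]
    ranks = rankdata(s, axis=1)
    n_pos = lb.sum(axis=1)
    n_neg = n - n_pos
    pos_rank_sum = (ranks * lb).sum(axis=1)
    aucs = (pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def operating_points(roc: RocResult, scores=None, labels=None) -> OperatingPoints:
    """P1/P2/P3 operating points from a ROC sweep.

    Accuracy uses observed prevalence. A P3 accuracy tie is broken toward
    the lower threshold (higher sensitivity), matching a screening bias.
    """
    se, sp, thr = roc.sensitivity, roc.specificity, roc.thresholds
    if scores is not None and labels is not None:
        scores, labels = _check_scores(scores, labels)
        n_pos = int(labels.sum())
        n_neg = labels.size - n_pos
    else:
        n_pos = n_neg = 1  # balanced accuracy fallback
    n = n_pos + n_neg
    acc = (se * n_pos + sp * n_neg) / n

    at_sp1 = np.flatnonzero(sp == 1.0)
    i1 = at_sp1[np.argmax(se[at_sp1])]
    at_se1 = np.flatnonzero(se == 1.0)
    i2 = at_se1[np.argmax(sp[at_se1])]
    # argmax returns the first maximum; thresholds are sorted descending in
    # threshold, i.e. ascending in SE -- reverse so ties pick the higher-SE point
    rev = acc[::-1]
    i3 = len(acc) - 1 - int(np.argmax(rev))
    return OperatingPoints(
        p1=(float(se[i1]), float(sp[i1]), float(acc[i1])),
        p2=(float(se[i2]), float(sp[i2]), float(acc[i2])),
        p3=(float(se[i3]), float(sp[i3]), float(acc[i3])),
        p3_threshold=float(thr[i3]),
    )


def pr_curve(scores, labels):
    """Precision/recall arrays over the descending unique-score sweep."""
    scores, labels = _check_scores(scores, labels)
    n_pos = int(labels.sum())
    uniq = np.unique(scores)[::-1]
    precision, recall = [], []
    for t in uniq:
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        precision.append(tp / (tp + fp) if tp + fp else 1.0)
        recall.append(tp / n_pos)
    return np.array(precision), np.array(recall)


def confusion_matrix(pred_labels, labels) -> np.ndarray:
    """2x2 counts [[TN, FP], [FN, TP]]."""
    pred = np.asarray(pred_labels, dtype=int)
    ref = np.asarray(labels, dtype=int)
    if pred.shape != ref.shape:
        raise ValueError("shape mismatch")
    m = np.zeros((2, 2), dtype=int)
    for p, r in zip(pred, ref):
        m[r, p] += 1
    return m
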