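"""Detection and classification metrics, plus feature-group statistics.

Detection: IoU, precision/recall from confusion counts, and single-class
average precision at IoU 0.5 (all-point interpolation, greedy
confidence-ordered one-to-one matching; duplicate hits on a matched truth
count as false positives).

Classification: accuracy, F1, AUC-ROC and AUC-PR (delegated to
scikit-learn; average precision is the all-point area under the PR curve).

Feature statistics: two-sided Mann-Whitney U (scipy, midrank ties,
U = min(U1, U2)) and the rank-biserial effect size r = 1 - 2U/(n1*n2),
reported as a magnitude, with a group-summary table in the style used for
the aspect-ratio / saturation comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "ConfusionCounts",
    "iou",
    "precision_recall",
    "accuracy_f1",
    "match_detections",
    "map50",
    "roc_pr_auc",
    "mann_whitney_u",
    "percent_reduction",
    "rank_biserial",
    "group_summary",
    "confusion_from_labels",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def iou(a, b) -> float:
    """Intersection-over-union of two pixel boxes (x0, y0, x1, y1)."""
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    area_a = max(0.0, ax1 - ax0) * max(0.0, ay1 - ay0)
    area_b = max(0.0, bx1 - bx0) * max(0.0, by1 - by0)
    if area_a == 0.0 or area_b == 0.0:
        warnings.warn("zero-area box in IoU", stacklevel=2)
        return 0.0
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    inter = max(0.0, iw) * max(0.0, ih)
    return inter / (area_a + area_b - inter)


def precision_recall(c: ConfusionCounts) -> tuple:
    """(precision, recall); NaN (never silent zero) on empty denominators."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else float("nan")
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else float("nan")
    if math.isnan(precision) or math.isnan(recall):
        warnings.warn("undefined precision/recall (zero denominator)", stacklevel=2)
    return precision, recall


def accuracy_f1(c: ConfusionCounts) -> tuple:
    if c.total == 0:
        raise ValueError("empty confusion counts")
    accuracy = (c.tp + c.tn) / c.total
    p, r = precision_recall(c)
    if math.isnan(p) or math.isnan(r) or (p + r) == 0:
        warnings.warn("F1 undefined; reporting 0", stacklevel=2)
        f1 = 0.0
    else:
        f1 = 2 * p * r / (p + r)
    return accuracy, f1


def confusion_from_labels(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    return ConfusionCounts(
        tp=int((y_true & y_pred).sum()),
        fp=int((~y_true & y_pred).sum()),
        fn=int((y_true & ~y_pred).sum()),
        tn=int((~y_true & ~y_pred).sum()),
    )


def match_detections(
    predictions: list, truths: list, iou_threshold: float = 0.5
) -> list:
    """Greedy one-to-one matching of one image's detections to its truths.

    `predictions`: list of (pixel box, confidence), `truths`: list of pixel
    boxes.  Returns a list of (confidence, is_tp) in descending-confidence
    order; each truth is matched at most once.
    """
    order = sorted(range(len(predictions)), key=lambda i: -predictions[i][1])
    matched: set = set()
    results = []
    for i in order:
        box, conf = predictions[i]
        best_j, best_iou = None, iou_threshold
        for j, tbox in enumerate(truths):
            if j in matched:
                continue
            v = iou(box, tbox)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j is not None:
            matched.add(best_j)
            results.append((conf, True))
        else:
            results.append((conf, False))
    return results


def map50(matches: list, n_truths: int) -> float:
    """All-point interpolated average precision from pooled match results.

    `matches`: (confidence, is_tp) pairs pooled over images; `n_truths`:
    total ground-truth count.  Undefined (NaN) when there are no truths.
    """
    if n_truths == 0:
        warnings.warn("AP undefined without ground truths", stacklevel=2)
        return float("nan")
    if not matches:
        return 0.0
    order = sorted(matches, key=lambda m: -m[0])
    tps = np.cumsum([m[1] for m in order])
    fps = np.cumsum([not m[1] for m in order])
    recall = tps / n_truths
    precision = tps / (tps + fps)
    # precision envelope, all-point interpolation
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, prec_env):
        ap += (r - r_prev) * p
        r_prev = r
    return float(ap)


def roc_pr_auc(probabilities, labels) -> tuple:
    """(AUC-ROC, AUC-PR); rejects single-class label vectors."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for ROC/PR areas")
    return (
        float(roc_auc_score(labels, probabilities)),
        float(average_precision_score(labels, probabilities)),
    )


def mann_whitney_u(x1, x2) -> float:
    """Two-sided Mann-Whitney U with midrank ties, reported as min(U1, U2)."""
    x1, x2 = np.asarray(x1, dtype=float), np.asarray(x2, dtype=float)
    if x1.size == 0 or x2.size == 0:
        raise ValueError("both samples must be non-empty")
    u1 = float(sps.mannwhitneyu(x1, x2, alternative="two-sided").statistic)
    u2 = x1.size * x2.size - u1
    return min(u1, u2)


def rank_biserial(u: float, n1: int, n2: int) -> float:
    """Magnitude of the rank-biserial effect size, r = |1 - 2U/(n1*n2)|."""
    if not (0 <= u <= n1 * n2):
        raise ValueError("U outside [0, n1*n2]")
    return abs(1.0 - 2.0 * u / (n1 * n2))


def percent_reduction(before: float, after: float) -> float:
    """Percent reduction from `before` to `after` (e.g. GFLOPs compression)."""
    if before <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (before - after) / before


def group_summary(
    estrus_values: dict, non_estrus_values: dict
) -> pd.DataFrame:
    """Feature-wise group statistics table.

    Arguments map feature name -> 1-D sample array for each group.  The
    table reports group means/SDs, Shapiro-Wilk and Levene screening
    p-values (pass-through from scipy), U, the rank-biserial r and the
    Mann-Whitney p-value.  Cohen's d (pooled SD) is included for
    completeness.
    """
    rows = []
    for feat in estrus_values:
        x1 = np.asarray(estrus_values[feat], dtype=float)
        x2 = np.asarray(non_estrus_values[feat], dtype=float)
        u = mann_whitney_u(x1, x2)
        p = float(sps.mannwhitneyu(x1, x2, alternative="two-sided").pvalue)
        n1, n2 = x1.size, x2.size
        pooled = math.sqrt(
            ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
        )
        rows.append(
            {
                "feature": feat,
                "estrus_mean": x1.mean(),
                "estrus_sd": x1.std(ddof=1),
                "non_estrus_mean": x2.mean(),
                "non_estrus_sd": x2.std(ddof=1),
                "shapiro_p_estrus": float(sps.shapiro(x1).pvalue),
                "shapiro_p_non_estrus": float(sps.shapiro(x2).pvalue),
                "levene_p": float(sps.levene(x1, x2).pvalue),
                "U": u,
                "rank_biserial_r": rank_biserial(u, n1, n2),
                "mannwhitney_p": p,
                "cohens_d": abs(x1.mean() - x2.mean()) / pooled if pooled > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def curve_table(probabilities, labels) -> pd.DataFrame:
    """Threshold sweep table (threshold, precision, recall, tpr, fpr) for CSV dumps."""
    labels = np.asarray(labels).astype(bool)
    probabilities = np.asarray(probabilities, dtype=float)
    rows = []
    for thr in np.unique(probabilities):
        pred = probabilities >= thr
        c = confusion_from_labels(labels, pred)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, r = precision_recall(c)
        fpr = c.fp / (c.fp + c.tn) if (c.fp + c.tn) else float("nan")
        rows.append(
            {"threshold": thr, "precision": p, "recall": r, "tpr": r, "fpr": fpr}
        )
    return pd.DataFrame(rows)


def evaluate_detections(
    per_image_predictions: list, per_image_truths: list, iou_threshold: float = 0.5
) -> dict:
    """Pool matches over images and report AP plus point precision/recall.

    `per_image_predictions[i]`: list of (pixel box, confidence) for image i;
    `per_image_truths[i]`: list of pixel truth boxes.
    """
    pooled = []
    n_truths = 0
    for preds, truths in zip(per_image_predictions, per_image_truths):
        pooled.extend(match_detections(preds, truths, iou_threshold))
        n_truths += len(truths)
    ap = map50(pooled, n_truths)
    tp = sum(1 for _, hit in pooled if hit)
    fp = len(pooled) - tp
    fn = n_truths - tp
    c = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=0)
    p, r = precision_recall(c)
    return {"map50": ap, "precision": p, "recall": r, "n_truths": n_truths}
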