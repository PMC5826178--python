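"""Counting accuracy evaluation: precision, recall and F1 from counts.

Given a ground-truth count GT, an estimated count EN and the number of true
positive detections TP, the score is

    P = TP / GT,    R = TP / EN,    F = 2 P R / (P + R).

Note the P and R formulas here divide by GT and EN respectively — swapped
relative to the usual precision/recall convention.  They are kept in this
form for compatibility with published adipocyte-counting benchmarks; F is
symmetric in P and R, so F1 values are unaffected by the swap (the CSV
columns follow the same naming).

For synthetic images with known truth, TP/FP/FN are derived automatically
by one-to-one label matching at IoU >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CountSummary", "f1_from_counts", "match_detections"]


@dataclass(frozen=True)
class CountSummary:
    """GT/EN/TP/FP/FN counts with the derived P, R and F rates in [0, 1]."""

    gt: int
    en: int
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def f1_from_counts(gt: int, en: int, tp: int) -> CountSummary:
    """Compute the count-based F1 summary from GT, EN and TP.

    Raises ``ValueError`` if GT or EN is zero (metric undefined) or if TP
    exceeds min(GT, EN).  FP = EN - TP and FN = GT - TP by definition;
    algebraically F = 2 TP / (GT + EN).
    """
    if gt <= 0 or en <= 0:
        raise ValueError(f"metric undefined for GT={gt}, EN={en}")
    if not 0 <= tp <= min(gt, en):
        raise ValueError(f"TP={tp} outside [0, min(GT={gt}, EN={en})]")
    p = tp / gt
    r = tp / en
    f = 0.0 if tp == 0 else 2 * p * r / (p + r)
    return CountSummary(
        gt=gt, en=en, tp=tp, fp=en - tp, fn=gt - tp, precision=p, recall=r, f1=f
    )


def match_detections(
    pred: np.ndarray, truth: np.ndarray, iou_threshold: float = 0.5
) -> tuple[int, int, int]:
    """Match predicted to true cells one-to-one; return (TP, FP, FN).

    Candidate pairs are every (pred, truth) label pair with nonzero pixel
    overlap and overlap/union >= ``iou_threshold``.  Pairs are matched
    greedily on descending pixel overlap (ties broken by label ids); each
    label participates in at most one match.  TP = matched pairs,
    FP = unmatched predictions, FN = unmatched truths.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"dimension mismatch: {pred.shape} vs {truth.shape}")

    n_pred = int(pred.max())
    n_truth = int(truth.max())
    pred_sizes = np.bincount(pred.ravel(), minlength=n_pred + 1)
    truth_sizes = np.bincount(truth.ravel(), minlength=n_truth + 1)

    both = (pred > 0) & (truth > 0)
    pairs, counts = np.unique(
        np.stack([pred[both], truth[both]]), axis=1, return_counts=True
    )

    candidates = []
    for (p_id, t_id), inter in zip(pairs.T, counts):
        union = pred_sizes[p_id] + truth_sizes[t_id] - inter
        if inter / union >= iou_threshold:
            candidates.append((int(inter), int(p_id), int(t_id)))
    candidates.sort(key=lambda x: (-x[0], x[1], x[2]))

    used_pred: set[int] = set()
    used_truth: set[int] = set()
    tp = 0
    for _, p_id, t_id in candidates:
        if p_id in used_pred or t_id in used_truth:
            continue
        used_pred.add(p_id)
        used_truth.add(t_id)
        tp += 1
    n_pred_labels = int(np.count_nonzero(pred_sizes[1:]))
    n_truth_labels = int(np.count_nonzero(truth_sizes[1:]))
    return tp, n_pred_labels - tp, n_truth_labels - tp
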