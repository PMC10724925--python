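"""Instance-level matching and precision/recall/AP metrics for label volumes.

A predicted cell and a ground-truth cell are matched when their 3D voxel
IoU strictly exceeds a threshold t; the matching is one-to-one, built
greedily in descending IoU (for t >= 0.5 candidate pairs are unique per
instance, so greedy is exactly optimal).  With TP matched pairs, FP
unmatched predictions and FN unmatched ground-truth cells:

    precision_t = TP / (TP + FP)
    recall_t    = TP / (TP + FN)
    AP_t        = TP / (TP + FN + FP)

and mAP averages AP over t in {0.25, 0.5, 0.75}.  Degenerate 0/0 ratios are
reported as 0, so empty predictions score 0 rather than erroring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MAP_THRESHOLDS = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class InstanceMatchResult:
    """One-to-one matching of predicted to ground-truth cells at IoU > t."""

    threshold: float
    tp: int
    fp: int
    fn: int
    matches: tuple  # of (pred label, gt label, IoU)


@dataclass(frozen=True)
class MetricReport:
    """Per-threshold precision/recall/AP plus mAP over the standard grid."""

    per_threshold: dict  # t -> (precision, recall, ap)
    map: float


def _as_data(volume) -> np.ndarray:
    if isinstance(volume, np.ndarray):
        return volume
    return np.asarray(getattr(volume, "data", volume))


def _pair_ious(pred: np.ndarray, gt: np.ndarray):
    """IoU for every overlapping (pred, gt) foreground pair, plus label sets."""
    pred_labels = np.unique(pred[pred > 0])
    gt_labels = np.unique(gt[gt > 0])
    fg = (pred > 0) & (gt > 0)
    pairs = {}
    if fg.any():
        pi = np.searchsorted(pred_labels, pred[fg])
        gi = np.searchsorted(gt_labels, gt[fg])
        inter = np.bincount(pi * gt_labels.size + gi,
                            minlength=pred_labels.size * gt_labels.size)
        inter = inter.reshape(pred_labels.size, gt_labels.size)
        pred_sizes = np.array([(pred == l).sum() for l in pred_labels])
        gt_sizes = np.array([(gt == l).sum() for l in gt_labels])
        ii, jj = np.nonzero(inter)
        for i, j in zip(ii, jj):
            union = pred_sizes[i] + gt_sizes[j] - inter[i, j]
            pairs[(int(pred_labels[i]), int(gt_labels[j]))] = inter[i, j] / union
    return pairs, pred_labels, gt_labels


def match_instances(pred, gt, t: float) -> InstanceMatchResult:
    """Greedy descending-IoU one-to-one matching of cells at IoU > t."""
    pred = _as_data(pred)
    gt = _as_data(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if not 0.0 <= t < 1.0:
        raise ValueError("threshold t must lie in [0, 1)")
    pairs, pred_labels, gt_labels = _pair_ious(pred, gt)
    candidates = sorted(
        ((iou, p, g) for (p, g), iou in pairs.items() if iou > t),
        key=lambda x: (-x[0], x[1], x[2]),
    )
    used_pred: set = set()
    used_gt: set = set()
    matches = []
    for iou, p, g in candidates:
        if p in used_pred or g in used_gt:
            continue
        used_pred.add(p)
        used_gt.add(g)
        matches.append((p, g, float(iou)))
    tp = len(matches)
    return InstanceMatchResult(
        threshold=t, tp=tp, fp=int(pred_labels.size) - tp,
        fn=int(gt_labels.size) - tp, matches=tuple(matches))


def _ratio(num: int, den: int) -> float:
    return num / den if den else 0.0


def metric_report(results) -> MetricReport:
    """Precision/recall/AP per threshold and mAP over {0.25, 0.5, 0.75}."""
    per = {}
    for r in results:
        per[r.threshold] = (
            _ratio(r.tp, r.tp + r.fp),
            _ratio(r.tp, r.tp + r.fn),
            _ratio(r.tp, r.tp + r.fn + r.fp),
        )
    missing = [t for t in MAP_THRESHOLDS if t not in per]
    if missing:
        raise ValueError(f"mAP needs thresholds {MAP_THRESHOLDS}; missing {missing}")
    return MetricReport(
        per_threshold=per,
        map=float(np.mean([per[t][2] for t in MAP_THRESHOLDS])),
    )


def evaluate(pred, gt, thresholds=MAP_THRESHOLDS) -> MetricReport:
    """Convenience wrapper: match at each threshold and build the report."""
    return metric_report([match_instances(pred, gt, t) for t in thresholds])


def mean_cell_iou(pred, gt) -> float:
    """Mean over ground-truth cells of the best IoU with any predicted cell.

    Cells with no overlapping prediction contribute 0.  Used to quantify
    shape recovery (e.g. after de-anisotropization) independently of a
    matching threshold.
    """
    pred = _as_data(pred)
    gt = _as_data(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    pairs, _, gt_labels = _pair_ious(pred, gt)
    if gt_labels.size == 0:
        return 0.0
    best = {int(g): 0.0 for g in gt_labels}
    for (_, g), iou in pairs.items():
        best[g] = max(best[g], float(iou))
    return float(np.mean(list(best.values())))
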