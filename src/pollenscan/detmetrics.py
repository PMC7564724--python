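"""Detection evaluation: IoU matching, per-class average precision, mAP.

Matching is class-specific and greedy in confidence order; AP is the area
under the precision-recall curve with all-point (continuous) interpolation.
The IoU threshold (default 0.5) and interpolation rule are recorded in the
result header so tabulated outputs are self-describing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stages import DETECTABLE_STAGES, StageClass, stage_from_any

Box = tuple[float, float, float, float]


def iou(box_a: Box, box_b: Box) -> float:
    """Intersection-over-union of two (x, y, w, h) boxes; 0 if disjoint."""
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    if min(aw, ah, bw, bh) <= 0:
        raise ValueError("boxes must have positive extent")
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    if inter == 0:
        return 0.0
    return inter / (aw * ah + bw * bh - inter)


def match(predictions, truths, iou_threshold=0.5):
    """Greedily label predictions TP/FP against ground-truth boxes.

    ``predictions`` must be sorted by confidence descending; each prediction
    claims the unmatched same-class truth of highest IoU if that IoU meets
    the threshold (ties on IoU go to the lower truth index), otherwise it is
    a false positive.  Returns (labels, unmatched_truth_indices) where
    labels[i] is True for TP.

    Predictions are anything with ``bbox`` and ``top_class``; truths anything
    with ``bbox`` and ``stage`` (or ``top_class``).
    """
    def _cls(obj):
        return stage_from_any(getattr(obj, "stage", None) or obj.top_class)

    taken = [False] * len(truths)
    labels = []
    for pred in predictions:
        pcls = stage_from_any(pred.top_class)
        best_j, best_iou = None, 0.0
        for j, t in enumerate(truths):
            if taken[j] or _cls(t) is not pcls:
                continue
            v = iou(pred.bbox, t.bbox)
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j is None:
            labels.append(False)
        else:
            taken[best_j] = True
            labels.append(True)
    unmatched = [j for j, t in enumerate(taken) if not t]
    return labels, unmatched


def average_precision(labels, n_truth: int) -> float:
    """AP from confidence-ordered TP/FP labels, all-point interpolation.

    Precision at each recall level is replaced by the maximum precision at
    that recall or beyond, and the interpolated curve is integrated over the
    recall increments.
    """
    if n_truth <= 0:
        raise ValueError("n_truth must be positive")
    labels = [bool(x) for x in labels]
    if not labels:
        return 0.0
    tp = np.cumsum(labels)
    fp = np.cumsum([not x for x in labels])
    precision = tp / (tp + fp)
    recall = tp / n_truth
    # interpolate: running max of precision from the right
    interp = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_recall = 0.0
    for r, p, is_tp in zip(recall, interp, labels):
        if is_tp:
            ap += (r - prev_recall) * p
            prev_recall = r
    return float(ap)


def mean_ap(per_class_ap, decimals: int = 2) -> float:
    """Unweighted arithmetic mean of per-class APs, as percent.

    Accepts APs either on [0, 1] or already in percent (detected by scale);
    reported rounded to ``decimals`` decimals.
    """
    vals = list(dict(per_class_ap).values()) if isinstance(per_class_ap, dict) else list(per_class_ap)
    if not vals:
        raise ValueError("need at least one defined class AP")
    arr = np.asarray(vals, float)
    if arr.max() <= 1.0:
        arr = arr * 100.0
    return float(np.round(arr.mean(), decimals))


@dataclass
class ClassResult:
    ap: float | None  # in [0,1]; None when no truth of this class
    n_truth: int
    tp: int
    fp: int
    fn: int


@dataclass
class EvaluationResult:
    """Per-class AP and mAP at a fixed IoU threshold."""

    iou_threshold: float
    interpolation: str
    per_class: dict  # StageClass -> ClassResult
    map: float  # mean over classes with n_truth > 0, in [0,1]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": s.short,
                "n_truth": cr.n_truth,
                "AP_pct": round(cr.ap * 100, 2) if cr.ap is not None else None,
                "TP": cr.tp,
                "FP": cr.fp,
                "FN": cr.fn,
            }
            for s, cr in self.per_class.items()
        ]
        rows.append(
            {"class": "mAP", "n_truth": sum(r["n_truth"] for r in rows),
             "AP_pct": round(self.map * 100, 2), "TP": None, "FP": None, "FN": None}
        )
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        doc = {
            "iou_threshold": self.iou_threshold,
            "interpolation": self.interpolation,
            "mAP": self.map,
            "per_class": {
                s.short: {
                    "AP": cr.ap, "n_truth": cr.n_truth,
                    "TP": cr.tp, "FP": cr.fp, "FN": cr.fn,
                }
                for s, cr in self.per_class.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def evaluate(predictions, truths, iou_threshold=0.5) -> EvaluationResult:
    """Evaluate detections against ground truth, per class and overall.

    Predictions are matched within their class only; classes without ground
    truth are recorded as undefined and excluded from the mAP.
    """
    preds = sorted(predictions, key=lambda p: -p.confidence)
    per_class = {}
    for cls in DETECTABLE_STAGES:
        cls_preds = [p for p in preds if stage_from_any(p.top_class) is cls]
        cls_truths = [
            t
            for t in truths
            if stage_from_any(getattr(t, "stage", None) or t.top_class) is cls
        ]
        n_truth = len(cls_truths)
        labels, unmatched = match(cls_preds, cls_truths, iou_threshold)
        tp = sum(labels)
        fp = len(labels) - tp
        if n_truth == 0:
            per_class[cls] = ClassResult(ap=None, n_truth=0, tp=0, fp=fp, fn=0)
            continue
        ap = average_precision(labels, n_truth)
        per_class[cls] = ClassResult(ap=ap, n_truth=n_truth, tp=tp, fp=fp, fn=n_truth - tp)
    defined = [cr.ap for cr in per_class.values() if cr.ap is not None]
    if not defined:
        raise ValueError("no class has ground truth; mAP undefined")
    return EvaluationResult(
        iou_threshold=iou_threshold,
        interpolation="all-point",
        per_class=per_class,
        map=float(np.mean(defined)),
    )
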