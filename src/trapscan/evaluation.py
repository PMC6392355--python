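"""Detection and sequence-label scoring.

Box-level matching follows the IoU >= 0.5 convention: a prediction is a
true positive iff it matches an unmatched ground-truth box of the same
class at IoU >= 0.5 (greedy assignment by descending IoU).  Sequence-level
rates are computed with the formulas as used in camera-trap filtering
reports: recall = TP/(TP+FN), precision = TP/(TP+FP),
FNR = FN/(FN+FP), TNR = TN/(TN+FP),
accuracy = (TP+TN)/(TP+TN+FP+FN).  Note the FNR denominator: the
conventional miss rate FN/(FN+TP) is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

IOU_MIN = 0.5

LABELS3 = ("human", "animal", "background")


def iou(box_a, box_b) -> float:
    """Intersection over union of half-open integer boxes (x0, y0, x1, y1)."""
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    area_a = (ax1 - ax0) * (ay1 - ay0)
    area_b = (bx1 - bx0) * (by1 - by0)
    if area_a <= 0 or area_b <= 0:
        raise ValueError("zero-area box")
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


@dataclass
class EvalReport:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    recall: float = math.nan
    precision: float = math.nan
    fnr: float = math.nan
    tnr: float = math.nan
    accuracy: float = math.nan
    confusion: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "recall": self.recall, "precision": self.precision,
            "fnr": self.fnr, "tnr": self.tnr, "accuracy": self.accuracy,
        }


def match_detections(
    gt_boxes: list[tuple],
    gt_classes: list[str],
    detections,
    iou_min: float = IOU_MIN,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of predictions to ground truth.

    Candidate pairs are ranked by descending IoU; a prediction is TP iff
    it matches at IoU >= ``iou_min`` with equal class.  Unmatched or
    class-mismatched predictions are FP; unmatched ground-truth objects
    are FN.  Returns (TP, FP, FN); invariant to prediction order.
    """
    pred_boxes, pred_classes = [], []
    for d in detections:
        if hasattr(d, "bbox"):
            pred_boxes.append(d.bbox)
            pred_classes.append(d.cls)
        else:  # (box, class) pairs
            pred_boxes.append(d[0])
            pred_classes.append(d[1])
    pairs = []
    for gi, (gb, gc) in enumerate(zip(gt_boxes, gt_classes)):
        for pi, (pb, pc) in enumerate(zip(pred_boxes, pred_classes)):
            if gc != pc:
                continue
            ov = iou(gb, pb)
            if ov >= iou_min:
                # tie-break on indices keeps the greedy pass deterministic
                pairs.append((-ov, gi, pi))
    pairs.sort()
    gt_used, pred_used = set(), set()
    tp = 0
    for _, gi, pi in pairs:
        if gi in gt_used or pi in pred_used:
            continue
        gt_used.add(gi)
        pred_used.add(pi)
        tp += 1
    fp = len(pred_boxes) - tp
    fn = len(gt_boxes) - tp
    return tp, fp, fn


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(
    tp: int, fp: int, fn: int, tn: int, conventional_fnr: bool = False
) -> EvalReport:
    """Point metrics from the four counts; undefined ratios are NaN."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    fnr = _ratio(fn, fn + tp) if conventional_fnr else _ratio(fn, fn + fp)
    return EvalReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        recall=_ratio(tp, tp + fn),
        precision=_ratio(tp, tp + fp),
        fnr=fnr,
        tnr=_ratio(tn, tn + fp),
        accuracy=_ratio(tp + tn, tp + tn + fp + fn),
    )


def sequence_confusion(
    gt_labels: list[str], pred_labels: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """3x3 confusion matrix over {human, animal, background} plus
    per-class precision/recall.  Rows are ground truth, columns predictions."""
    if len(gt_labels) != len(pred_labels):
        raise ValueError("label list length mismatch")
    mat = pd.DataFrame(0, index=list(LABELS3), columns=list(LABELS3))
    for g, p in zip(gt_labels, pred_labels):
        mat.loc[g, p] += 1
    per_class = pd.DataFrame(index=list(LABELS3), columns=["precision", "recall"], dtype=float)
    for c in LABELS3:
        per_class.loc[c, "precision"] = _ratio(mat.loc[c, c], mat[c].sum())
        per_class.loc[c, "recall"] = _ratio(mat.loc[c, c], mat.loc[c].sum())
    return mat, per_class


def binary_object_metrics(
    gt_labels: list[str], pred_labels: list[str], conventional_fnr: bool = False
) -> EvalReport:
    """Sequence-level object-vs-background counts and rates.

    Positive = sequence contains an object (human or animal) and is
    predicted to contain one; negative = background.
    """
    tp = fp = fn = tn = 0
    for g, p in zip(gt_labels, pred_labels):
        g_obj, p_obj = g != "background", p != "background"
        if g_obj and p_obj:
            tp += 1
        elif not g_obj and p_obj:
            fp += 1
        elif g_obj and not p_obj:
            fn += 1
        else:
            tn += 1
    rep = compute_metrics(tp, fp, fn, tn, conventional_fnr=conventional_fnr)
    rep.confusion = sequence_confusion(gt_labels, pred_labels)[0]
    return rep


# ---------------------------------------------------------------------------
# ground-truth CSV I/O  (image, x_min, y_min, x_max, y_max, class)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"image", "x_min", "y_min", "x_max", "y_max", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ground truth missing columns: {sorted(missing)}")
    return df


def write_ground_truth(df: pd.DataFrame, path: str | Path):
    df.to_csv(path, index=False)
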