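"""Instance-segmentation evaluation: point-set IoU average precision.

Predicted instances are matched to ground truth greedily in order of
descending confidence (ScanNet-style): each prediction claims the unmatched
ground-truth instance of the same class with the highest IoU at or above the
threshold.  Precision-recall points accumulate along that ranking, pooled
over all test scenes per class; AP at one threshold is the area under the
monotonized precision envelope.  AP averages the thresholds 0.50:0.05:0.95;
AP50 and AP25 are the fixed-threshold values; "overall" is the unweighted
mean over classes present in the ground truth.  A 3×3 semantic confusion
matrix (rows = ground truth, columns = prediction) accompanies the scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cloud import LEAF, STEM, LabeledCloud
from .clustering import InstancePrediction

__all__ = ["EvalResult", "instance_iou", "match_and_score", "average_precision",
           "evaluate", "semantic_confusion", "scene_instances", "AP_THRESHOLDS"]

AP_THRESHOLDS = np.arange(0.50, 0.951, 0.05)
CLASS_NAMES = {STEM: "stem", LEAF: "leaf"}


@dataclass
class EvalResult:
    per_class: Dict[str, Dict[str, float]]
    overall: Dict[str, float]
    matches: List[Tuple[int, int, float]]
    confusion: np.ndarray
    absent_classes: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "overall": self.overall,
            "confusion": self.confusion.tolist(),
            "absent_classes": self.absent_classes,
        }

    def to_table(self) -> str:
        """Plain-text table: class rows × AP / AP50 / AP25 columns."""
        rows = [f"{'':10s} {'AP':>8s} {'AP50':>8s} {'AP25':>8s}"]
        for name in ("stem", "leaf"):
            if name in self.per_class:
                m = self.per_class[name]
                rows.append(f"{name.capitalize():10s} {m['AP']:8.4f} "
                            f"{m['AP50']:8.4f} {m['AP25']:8.4f}")
        m = self.overall
        rows.append(f"{'Overall':10s} {m['AP']:8.4f} {m['AP50']:8.4f} {m['AP25']:8.4f}")
        return "\n".join(rows)


def instance_iou(pred_set: np.ndarray, gt_set: np.ndarray) -> float:
    """Point-set intersection over union; 0 when both sets are empty."""
    a, b = set(map(int, pred_set)), set(map(int, gt_set))
    union = len(a | b)
    return len(a & b) / union if union else 0.0


@dataclass
class _Instance:
    points: np.ndarray
    cls: int
    confidence: float = 1.0
    scene: int = 0


def scene_instances(cloud: LabeledCloud, pred: Optional[InstancePrediction] = None,
                    scene: int = 0) -> Tuple[List[_Instance], List[_Instance]]:
    """Instances of one scene, ground truth and (optionally) prediction.

    Ground truth: leaf instances come from instance ids ≥ 0; all stem points
    form one stem instance.  Predicted: leaf instances are clusters; the
    stem instance (if any) is the grouped stem prediction.
    """
    gt: List[_Instance] = []
    if cloud.instance is not None:
        for k in np.unique(cloud.instance[cloud.instance >= 0]):
            gt.append(_Instance(np.flatnonzero(cloud.instance == k), LEAF, 1.0, scene))
    if cloud.semantic is not None and (cloud.semantic == STEM).any():
        gt.append(_Instance(np.flatnonzero(cloud.semantic == STEM), STEM, 1.0, scene))
    preds: List[_Instance] = []
    if pred is not None:
        ids = pred.instance_ids
        for k in range(int(ids.max()) + 1 if ids.size and ids.max() >= 0 else 0):
            cls = STEM if (pred.stem_instance_id is not None
                           and k == pred.stem_instance_id) else LEAF
            conf = float(pred.confidences[k]) if k < len(pred.confidences) else 1.0
            preds.append(_Instance(np.flatnonzero(ids == k), cls, conf, scene))
    return preds, gt


def match_and_score(predictions: Sequence[_Instance], ground_truth: Sequence[_Instance],
                    cls: int, iou_threshold: float):
    """Greedy confidence-ranked matching at one IoU threshold.

    Returns (tp flags along the ranking, number of ground-truth instances,
    match list of (pred index, gt index, IoU)).
    """
    preds = [p for p in predictions if p.cls == cls]
    gts = [g for g in ground_truth if g.cls == cls]
    order = sorted(range(len(preds)),
                   key=lambda i: (-preds[i].confidence, -len(preds[i].points), i))
    matched_gt: set = set()
    tp = np.zeros(len(preds), dtype=bool)
    matches = []
    for rank, i in enumerate(order):
        best_iou, best_j = 0.0, -1
        for j, g in enumerate(gts):
            if j in matched_gt or g.scene != preds[i].scene:
                continue
            iou = instance_iou(preds[i].points, g.points)
            if iou >= iou_threshold and iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0:
            matched_gt.add(best_j)
            tp[rank] = True
            matches.append((i, best_j, best_iou))
    return tp, len(gts), matches


def average_precision(tp: np.ndarray, n_gt: int) -> float:
    """All-point interpolated AP from ranked true-positive flags."""
    if n_gt == 0:
        return float("nan")
    if len(tp) == 0:
        return 0.0
    cum_tp = np.cumsum(tp)
    precision = cum_tp / np.arange(1, len(tp) + 1)
    recall = cum_tp / n_gt
    # precision envelope, integrated over every recall step
    r = np.concatenate([[0.0], recall, [recall[-1]]])
    p = np.concatenate([[0.0], precision, [0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    steps = np.flatnonzero(r[1:] != r[:-1])
    return float(np.sum((r[steps + 1] - r[steps]) * p[steps + 1]))


def evaluate(pred_scenes: Sequence[InstancePrediction],
             gt_scenes: Sequence[LabeledCloud]) -> EvalResult:
    """Pooled-scene evaluation over the stem and leaf classes."""
    if len(pred_scenes) != len(gt_scenes):
        raise ValueError("prediction/ground-truth scene counts differ")
    all_preds: List[_Instance] = []
    all_gts: List[_Instance] = []
    confusion = np.zeros((3, 3), dtype=np.int64)
    for s, (pred, cloud) in enumerate(zip(pred_scenes, gt_scenes)):
        p, g = scene_instances(cloud, pred, scene=s)
        all_preds.extend(p)
        all_gts.extend(g)
        if cloud.semantic is not None:
            confusion += semantic_confusion(pred.semantic_pred, cloud.semantic)
    per_class: Dict[str, Dict[str, float]] = {}
    absent: List[str] = []
    matches: List[Tuple[int, int, float]] = []
    for cls, name in CLASS_NAMES.items():
        if not any(g.cls == cls for g in all_gts):
            absent.append(name)
            continue
        aps = []
        for thr in AP_THRESHOLDS:
            tp, n_gt, mlist = match_and_score(all_preds, all_gts, cls, thr)
            aps.append(average_precision(tp, n_gt))
            if abs(thr - 0.5) < 1e-9:
                matches.extend(mlist)
        tp25, n_gt, _ = match_and_score(all_preds, all_gts, cls, 0.25)
        per_class[name] = {
            "AP": float(np.mean(aps)),
            "AP50": aps[0],
            "AP25": average_precision(tp25, n_gt),
        }
    if per_class:
        overall = {k: float(np.mean([m[k] for m in per_class.values()]))
                   for k in ("AP", "AP50", "AP25")}
    else:
        overall = {"AP": float("nan"), "AP50": float("nan"), "AP25": float("nan")}
    return EvalResult(per_class, overall, matches, confusion, absent)


def semantic_confusion(pred_labels: np.ndarray, gt_labels: np.ndarray) -> np.ndarray:
    """3×3 count matrix; entry (g, p) = points with ground truth g predicted p."""
    pred_labels = np.asarray(pred_labels)
    gt_labels = np.asarray(gt_labels)
    if pred_labels.shape != gt_labels.shape:
        raise ValueError("label arrays differ in length")
    for arr in (pred_labels, gt_labels):
        if arr.size and (arr.min() < 0 or arr.max() > 2):
            raise ValueError("labels out of range {0, 1, 2}")
    out = np.zeros((3, 3), dtype=np.int64)
    np.add.at(out, (gt_labels, pred_labels), 1)
    return out
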