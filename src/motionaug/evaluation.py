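"""PASCAL-style detection metrics: IOU, per-class AP, mAP suites.

A detection is a true positive when its best-IOU unmatched ground-truth
box of the same class on the same image reaches the IOU threshold;
matching is greedy in descending score order and each ground-truth box
can be claimed once. Average precision is the area under the all-point
interpolated precision-recall curve (precision = TP / (TP + FP)), and
mAP at a threshold is the unweighted mean of per-class AP over classes
with at least one ground-truth box. The COCO-style summary mAP@50:95
averages the ten thresholds 0.50, 0.55, ..., 0.95.

Tie-breaking is fixed and documented for reproducibility: equal scores
keep detection input order (stable sort); equal IOUs during matching
prefer the earlier ground-truth box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from motionaug.sequence_io import Annotation, _parse_box_lines

__all__ = [
    "Detection",
    "EvalResult",
    "iou",
    "average_precision",
    "map_suite",
    "read_detections",
    "write_detections",
    "COCO_THRESHOLDS",
]

COCO_THRESHOLDS: tuple[float, ...] = tuple(round(0.5 + 0.05 * i, 2) for i in range(10))

Box = tuple[float, float, float, float]  # (x1, y1, x2, y2), half-open


@dataclass
class Detection:
    """A predicted box: class, half-open corner geometry, confidence."""

    class_id: int
    box: Box
    score: float
    image_ref: str = ""

    def __post_init__(self) -> None:
        x1, y1, x2, y2 = self.box
        if x2 <= x1 or y2 <= y1:
            raise ValueError(f"detection box must have positive area, got {self.box}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


@dataclass
class EvalResult:
    """Per-class AP at each threshold plus the three summary mAPs."""

    ap: dict[float, dict[int, float]]  # threshold -> class -> AP
    map50: float
    map75: float
    map5095: float
    tp_fp: dict[float, dict[int, tuple[int, int]]] = field(default_factory=dict)
    unmatched_det_classes: list[int] = field(default_factory=list)

    def map_at(self, threshold: float) -> float:
        per_class = self.ap[threshold]
        return float(np.mean(list(per_class.values()))) if per_class else float("nan")

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "map50": self.map50,
                "map75": self.map75,
                "map5095": self.map5095,
                "ap": {f"{t:.2f}": {str(c): v for c, v in d.items()} for t, d in self.ap.items()},
                "tp_fp": {
                    f"{t:.2f}": {str(c): list(v) for c, v in d.items()} for t, d in self.tp_fp.items()
                },
                "unmatched_det_classes": self.unmatched_det_classes,
            },
            indent=2,
            sort_keys=True,
        )


def iou(box_a: Box, box_b: Box) -> float:
    """Intersection area over union area of two half-open corner boxes."""
    ax1, ay1, ax2, ay2 = box_a
    bx1, by1, bx2, by2 = box_b
    area_a = (ax2 - ax1) * (ay2 - ay1)
    area_b = (bx2 - bx1) * (by2 - by1)
    if area_a <= 0 or area_b <= 0:
        raise ValueError("boxes must have positive area")
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


def _annotation_box(a: Annotation, height: int, width: int) -> Box:
    return a.to_corners(height, width)


def _match_detections(
    dets: list[Detection], gt_boxes: dict[str, list[Box]], iou_thresh: float
) -> list[bool]:
    """Greedy TP/FP flags in descending-score order (input order on ties)."""
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)  # stable
    matched: dict[str, set[int]] = {ref: set() for ref in gt_boxes}
    flags = [False] * len(dets)
    for rank, i in enumerate(order):
        det = dets[i]
        candidates = gt_boxes.get(det.image_ref, [])
        best_iou, best_j = 0.0, -1
        for j, gbox in enumerate(candidates):
            if j in matched.get(det.image_ref, set()):
                continue
            v = iou(det.box, gbox)
            if v > best_iou:  # strict: IOU ties keep the earlier GT
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_thresh:
            matched[det.image_ref].add(best_j)
            flags[rank] = True
    return flags  # in descending-score order


def _ap_from_flags(flags: list[bool], n_gt: int) -> float:
    """All-point interpolated area under the precision-recall curve."""
    if n_gt == 0:
        raise ValueError("AP undefined with no ground truth")
    if not flags:
        return 0.0
    tp = np.cumsum(flags)
    fp = np.cumsum([not f for f in flags])
    recall = tp / n_gt
    precision = tp / (tp + fp)
    # precision envelope + sum over recall steps
    mrec = np.concatenate([[0.0], recall, [1.0]])
    mpre = np.concatenate([[0.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.nonzero(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def average_precision(
    dets: list[Detection],
    gts: list[Annotation],
    class_id: int,
    iou_thresh: float,
    image_size: tuple[int, int] = (1, 1),
) -> float:
    """AP for one class at one IOU threshold.

    ``image_size=(H, W)`` converts normalized ground-truth boxes into
    the pixel frame of the detections; with the default (1, 1) both
    live in normalized coordinates. Raises ``ValueError`` if the class
    has no ground truth (such classes are excluded from mAP).
    """
    h, w = image_size
    cls_dets = [d for d in dets if d.class_id == class_id]
    cls_gts = [g for g in gts if g.class_id == class_id]
    if not cls_gts:
        raise ValueError(f"class {class_id} has no ground truth; AP undefined")
    gt_boxes: dict[str, list[Box]] = {}
    for g in cls_gts:
        gt_boxes.setdefault(g.image_ref, []).append(_annotation_box(g, h, w))
    flags = _match_detections(cls_dets, gt_boxes, iou_thresh)
    return _ap_from_flags(flags, len(cls_gts))


def map_suite(
    dets: list[Detection],
    gts: list[Annotation],
    thresholds: tuple[float, ...] | None = None,
    image_size: tuple[int, int] = (1, 1),
) -> EvalResult:
    """Per-class AP and the mAP@50 / @75 / @50:95 summary metrics.

    Classes with ground truth but no detections score AP 0; classes
    with detections but no ground truth contribute nothing to mAP and
    are listed in ``unmatched_det_classes``.
    """
    if not gts:
        raise ValueError("cannot evaluate with empty ground truth")
    gt_classes = sorted({g.class_id for g in gts})
    det_only = sorted({d.class_id for d in dets} - set(gt_classes))
    if thresholds is None:
        thresholds = tuple(sorted(set(COCO_THRESHOLDS) | {0.5, 0.75}))

    ap: dict[float, dict[int, float]] = {}
    tp_fp: dict[float, dict[int, tuple[int, int]]] = {}
    for thr in thresholds:
        ap[thr] = {}
        tp_fp[thr] = {}
        for cls in gt_classes:
            ap[thr][cls] = average_precision(dets, gts, cls, thr, image_size)
            cls_dets = [d for d in dets if d.class_id == cls]
            gt_boxes: dict[str, list[Box]] = {}
            h, w = image_size
            for g in gts:
                if g.class_id == cls:
                    gt_boxes.setdefault(g.image_ref, []).append(_annotation_box(g, h, w))
            flags = _match_detections(cls_dets, gt_boxes, thr)
            tp_fp[thr][cls] = (int(sum(flags)), int(len(flags) - sum(flags)))

    def _map(thr: float) -> float:
        vals = list(ap[thr].values())
        return float(np.mean(vals)) if vals else float("nan")

    coco = [t for t in COCO_THRESHOLDS if t in ap]
    map5095 = float(np.mean([_map(t) for t in coco])) if coco else float("nan")
    return EvalResult(
        ap=ap,
        map50=_map(0.5) if 0.5 in ap else float("nan"),
        map75=_map(0.75) if 0.75 in ap else float("nan"),
        map5095=map5095,
        tp_fp=tp_fp,
        unmatched_det_classes=det_only,
    )


def read_detections(path: str | Path, image_ref: str = "", image_size: tuple[int, int] = (1, 1)) -> list[Detection]:
    """Parse a YOLO-dialect detection file (``class cx cy w h score``).

    Lines without a score default to confidence 1.0, so ground-truth
    files can double as perfect-detector input.
    """
    path = Path(path)
    ref = image_ref or path.stem
    h, w = image_size
    out = []
    for cls, cx, cy, bw, bh, score in _parse_box_lines(path, expect_score=True):
        box = ((cx - bw / 2) * w, (cy - bh / 2) * h, (cx + bw / 2) * w, (cy + bh / 2) * h)
        out.append(Detection(class_id=cls, box=box, score=1.0 if score is None else score, image_ref=ref))
    return out


def write_detections(dets: list[Detection], path: str | Path, image_size: tuple[int, int] = (1, 1)) -> None:
    h, w = image_size
    lines = []
    for d in dets:
        x1, y1, x2, y2 = d.box
        cx, cy = (x1 + x2) / 2 / w, (y1 + y2) / 2 / h
        bw, bh = (x2 - x1) / w, (y2 - y1) / h
        lines.append(f"{d.class_id} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f} {d.score:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
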