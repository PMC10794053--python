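"""Detection and counting evaluation protocol.

Detection quality is scored per image by greedy IoU matching in descending
confidence (each ground-truth box claimed at most once, duplicates become
false detections), aggregated into precision, recall and average precision
(AP) as the area under the all-point interpolated precision–recall curve.
Counting quality is scored by MAE and MSE over per-image counts.  The
dataset splitter reproduces the 7 : 1.5 : 1.5 train/validation/test
protocol with floor rounding (train floor of its share, validation floor
of its share of the remainder, test the rest).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .annotations_io import Box, BoxAnnotation

__all__ = [
    "DetectionMatchResult",
    "PRCurve",
    "CountMetrics",
    "iou",
    "match_detections",
    "pr_and_ap",
    "tally_detections",
    "count_metrics",
    "split_dataset",
    "load_reference_tally",
]


@dataclass
class DetectionMatchResult:
    """TP/FP/FN tallies of one image at a fixed IoU threshold."""

    image_id: str
    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError(f"{self.image_id}: negative tally")
        if len(self.matched_pairs) != self.tp:
            raise ValueError(f"{self.image_id}: matched pair list does not equal TP")

    @property
    def n_gt(self) -> int:
        return self.tp + self.fn

    @property
    def n_pred(self) -> int:
        return self.tp + self.fp


@dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray
    ap: float

    def __post_init__(self) -> None:
        self.recall = np.asarray(self.recall, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)
        if self.recall.size and (np.diff(self.recall) < -1e-12).any():
            raise ValueError("recall must be non-decreasing along the curve")
        if not (0.0 <= self.ap <= 1.0):
            raise ValueError(f"AP {self.ap} outside [0, 1]")


@dataclass
class CountMetrics:
    mae: float
    mse: float
    n: int

    def __post_init__(self) -> None:
        if self.mae < 0 or self.mse < 0:
            raise ValueError("error metrics cannot be negative")
        if self.mae > np.sqrt(self.mse) + 1e-9:
            raise ValueError("MAE exceeds sqrt(MSE); inconsistent inputs")


def iou(box_a: Box | tuple, box_b: Box | tuple) -> float:
    """Intersection-over-union of two half-open boxes; 0 when disjoint."""
    a = box_a if isinstance(box_a, Box) else Box(*box_a)
    b = box_b if isinstance(box_b, Box) else Box(*box_b)
    ix = max(0.0, min(a.xmax, b.xmax) - max(a.xmin, b.xmin))
    iy = max(0.0, min(a.ymax, b.ymax) - max(a.ymin, b.ymin))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def match_detections(
    pred: BoxAnnotation, gt: BoxAnnotation, iou_threshold: float = 0.5
) -> DetectionMatchResult:
    """Greedy one-to-one matching of predictions to ground truth.

    Predictions are visited in descending confidence; each is a true
    positive iff its best-IoU *unclaimed* GT box reaches the threshold,
    otherwise a false positive (so duplicate detections of one crown count
    as false, matching how repeated detections are scored).
    """
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError("iou_threshold must lie in (0, 1)")
    for i, p in enumerate(pred.boxes):
        if p.confidence is None:
            raise ValueError(f"prediction {i} lacks a confidence score")
    order = sorted(range(len(pred.boxes)), key=lambda i: -pred.boxes[i].confidence)
    claimed: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    fp = 0
    for i in order:
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gt.boxes):
            if j in claimed:
                continue
            v = iou(pred.boxes[i], g)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            claimed.add(best_j)
            pairs.append((i, best_j, best_iou))
        else:
            fp += 1
    return DetectionMatchResult(
        image_id=pred.image_id,
        tp=len(pairs),
        fp=fp,
        fn=len(gt.boxes) - len(pairs),
        matched_pairs=pairs,
    )


def pr_and_ap(
    preds: list[BoxAnnotation], gts: list[BoxAnnotation], iou_threshold: float = 0.5
) -> PRCurve:
    """Precision–recall curve and AP across a set of images.

    Predictions from all images are pooled and swept from the highest
    confidence down; AP is the area under the step-wise curve with the
    standard precision envelope (all-point interpolation).
    """
    gt_by_id = {g.image_id: g for g in gts}
    total_gt = sum(len(g.boxes) for g in gts)
    if total_gt == 0:
        raise ValueError("no ground-truth boxes; recall undefined")
    entries = []  # (confidence, image_id, pred index)
    for p in preds:
        for i, box in enumerate(p.boxes):
            if box.confidence is None:
                raise ValueError(f"{p.image_id}: prediction {i} lacks confidence")
            entries.append((box.confidence, p.image_id, i))
    entries.sort(key=lambda t: -t[0])
    claimed: dict[str, set[int]] = {g: set() for g in gt_by_id}
    pred_by_id = {p.image_id: p for p in preds}
    tp_flags = []
    for conf, img, i in entries:
        gt = gt_by_id.get(img)
        box = pred_by_id[img].boxes[i]
        best_j, best_iou = -1, 0.0
        if gt is not None:
            for j, g in enumerate(gt.boxes):
                if j in claimed[img]:
                    continue
                v = iou(box, g)
                if v > best_iou:
                    best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            claimed[img].add(best_j)
            tp_flags.append(1.0)
        else:
            tp_flags.append(0.0)
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(1.0 - np.asarray(tp_flags))
    recall = tp_cum / total_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    # precision envelope: best precision achievable at recall >= r
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - r_prev) * p
        r_prev = r
    return PRCurve(recall=recall, precision=precision, ap=float(ap))


def tally_detections(results: list[DetectionMatchResult]) -> dict:
    """Column-wise sums of per-image tallies (total, correct, false, missed)."""
    if not results:
        raise ValueError("no per-image results to tally")
    for r in results:
        if r.tp + r.fn != r.n_gt or r.tp + r.fp != r.n_pred:
            raise ValueError(f"inconsistent tally for image {r.image_id}")
    return {
        "total": sum(r.n_gt for r in results),
        "correct": sum(r.tp for r in results),
        "false": sum(r.fp for r in results),
        "missed": sum(r.fn for r in results),
    }


def count_metrics(pred_counts, gt_counts) -> CountMetrics:
    """MAE and MSE between predicted and true per-image counts."""
    p = np.asarray(pred_counts, dtype=float).ravel()
    g = np.asarray(gt_counts, dtype=float).ravel()
    if p.size != g.size:
        raise ValueError(f"length mismatch: {p.size} predictions vs {g.size} truths")
    if p.size == 0:
        raise ValueError("need at least one image")
    err = p - g
    return CountMetrics(mae=float(np.abs(err).mean()), mse=float((err**2).mean()), n=p.size)


def split_dataset(
    ids: list, ratios: tuple[float, float, float] = (7.0, 1.5, 1.5), seed: int = 0
) -> tuple[list, list, list]:
    """Deterministic shuffled train/val/test partition.

    Train takes the floor of its share of N; validation takes the floor of
    its share of what remains; test takes the rest.  The three lists are
    disjoint and cover ``ids`` exactly.
    """
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    if len(ids) < 3:
        raise ValueError("need at least 3 ids to split three ways")
    r_train, r_val, r_test = ratios
    if min(ratios) <= 0:
        raise ValueError("ratios must be positive")
    total = r_train + r_val + r_test
    order = np.random.default_rng(seed).permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n = len(ids)
    n_train = int(np.floor(n * r_train / total))
    n_val = int(np.floor((n - n_train) * r_val / (r_val + r_test)))
    train = shuffled[:n_train]
    val = shuffled[n_train : n_train + n_val]
    test = shuffled[n_train + n_val :]
    return train, val, test


def load_reference_tally() -> pd.DataFrame:
    """Published per-image crown-detection tally from a UAV survey benchmark.

    26 manually audited test images; for each of four detectors the table
    lists correct, false and missed detections against the total box count.
    Shipped with the package as plain CSV for offline evaluation demos.
    """
    with resources.files("shootcount.data").joinpath("crown_detection_tally.csv").open() as fh:
        return pd.read_csv(fh)
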