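"""Segmentation and registration evaluation metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transforms import RigidTransform2D


@dataclass
class SegmentationMetrics:
    """Overall pixel accuracy, per-class Dice, and the confusion table."""

    overall_accuracy: float
    dice: dict[int, float]
    confusion: np.ndarray
    class_codes: np.ndarray
    n_pixels: int


def dice(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Overlap ``2|A & B| / (|A| + |B|)``; two empty masks score 1."""
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(truth_mask, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask dimensions differ")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def overall_accuracy(pred_labels: np.ndarray, truth_labels: np.ndarray,
                     region_mask: np.ndarray | None = None
                     ) -> SegmentationMetrics:
    """Pixel accuracy inside an optional region, with confusion and Dice.

    The confusion table rows index the truth class, columns the
    prediction; its trace over its total is the accuracy.
    """
    pred = np.asarray(pred_labels, dtype=int)
    truth = np.asarray(truth_labels, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("label map dimensions differ")
    region = np.ones(pred.shape, dtype=bool) if region_mask is None \
        else np.asarray(region_mask, dtype=bool)
    if region.shape != pred.shape:
        raise ValueError("region mask dimensions differ")
    if not region.any():
        raise ValueError("evaluation region is empty")
    p = pred[region]
    t = truth[region]
    codes = np.unique(np.concatenate([p, t]))
    index = {c: i for i, c in enumerate(codes)}
    confusion = np.zeros((codes.size, codes.size), dtype=int)
    np.add.at(confusion,
              (np.vectorize(index.get)(t), np.vectorize(index.get)(p)), 1)
    acc = float(np.trace(confusion)) / confusion.sum()
    dice_per_class = {}
    for c, i in index.items():
        denom = confusion[i, :].sum() + confusion[:, i].sum()
        dice_per_class[int(c)] = (2.0 * confusion[i, i] / denom
                                  if denom else 1.0)
    return SegmentationMetrics(overall_accuracy=acc, dice=dice_per_class,
                               confusion=confusion, class_codes=codes,
                               n_pixels=int(region.sum()))


def probe_grid(shape, n_per_axis: int = 5) -> np.ndarray:
    """Fixed probe points spanning the central half of the grid."""
    h, w = shape[:2]
    rows = np.linspace(0.25 * (h - 1), 0.75 * (h - 1), n_per_axis)
    cols = np.linspace(0.25 * (w - 1), 0.75 * (w - 1), n_per_axis)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1)


def target_registration_error(est: RigidTransform2D, truth: RigidTransform2D,
                              probe_points: np.ndarray, center) -> float:
    """Mean distance between truth- and estimate-mapped probe points."""
    pts = np.atleast_2d(np.asarray(probe_points, dtype=float))
    if pts.shape[0] < 1:
        raise ValueError("at least one probe point is required")
    d = est.apply(pts, center) - truth.apply(pts, center)
    return float(np.linalg.norm(d, axis=1).mean())
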