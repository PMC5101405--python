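"""OTB-style tracking metrics: precision and success plots.

Two standard curves summarize a tracker against ground truth:

* the precision plot — the fraction of frames whose predicted box center
  lies within a pixel threshold of the true center, reported at the
  representative 20-px threshold;
* the success plot — the fraction of frames whose predicted box IoU
  exceeds a threshold swept over [0, 1], ranked by the area under the
  curve (the mean of the success rate over the standard 21-point grid,
  with a strict ">" at each threshold).
"""

from __future__ import annotations

import numpy as np

from .tracker import ObjectState, iou

__all__ = ["center_error", "overlap", "precision_score", "precision_curve",
           "success_auc", "success_curve", "evaluate_trajectories"]

PRECISION_THRESHOLD = 20.0
SUCCESS_GRID = np.linspace(0.0, 1.0, 21)


def _check_lengths(pred, gt):
    if len(pred) != len(gt):
        raise ValueError(f"trajectory lengths differ: {len(pred)} vs {len(gt)}")
    if len(pred) == 0:
        raise ValueError("empty trajectories")


def center_error(pred: list[ObjectState], gt: list[ObjectState]) -> np.ndarray:
    """Per-frame Euclidean distance between box centers, in pixels."""
    _check_lengths(pred, gt)
    pc = np.array([p.center for p in pred])
    gc = np.array([g.center for g in gt])
    return np.hypot(*(pc - gc).T)


def overlap(pred: list[ObjectState], gt: list[ObjectState]) -> np.ndarray:
    """Per-frame intersection-over-union, each in [0, 1]."""
    _check_lengths(pred, gt)
    return np.array([iou(p, g) for p, g in zip(pred, gt)])


def precision_curve(errors, thresholds=None) -> tuple[np.ndarray, np.ndarray]:
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("empty error sequence")
    if thresholds is None:
        thresholds = np.arange(0.0, 51.0)
    thresholds = np.asarray(thresholds, dtype=float)
    frac = (errors[None, :] <= thresholds[:, None]).mean(axis=1)
    return thresholds, frac


def precision_score(errors, threshold: float = PRECISION_THRESHOLD) -> float:
    """Fraction of frames with center error <= threshold (default 20 px)."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("empty error sequence")
    return float((errors <= threshold).mean())


def success_curve(ious, thresholds=None) -> tuple[np.ndarray, np.ndarray]:
    ious = np.asarray(ious, dtype=float)
    if ious.size == 0:
        raise ValueError("empty IoU sequence")
    if thresholds is None:
        thresholds = SUCCESS_GRID
    thresholds = np.asarray(thresholds, dtype=float)
    frac = (ious[None, :] > thresholds[:, None]).mean(axis=1)
    return thresholds, frac


def success_auc(ious) -> float:
    """Mean success rate over the 21-threshold grid (strict overlap)."""
    _, frac = success_curve(ious)
    return float(frac.mean())


def evaluate_trajectories(pred, gt) -> dict:
    """One-call report: errors, IoUs, precision@20, success AUC and curves."""
    errors = center_error(pred, gt)
    ious = overlap(pred, gt)
    pth, pcurve = precision_curve(errors)
    sth, scurve = success_curve(ious)
    return dict(
        n_frames=len(pred),
        mean_center_error=float(errors.mean()),
        mean_iou=float(ious.mean()),
        precision_20=precision_score(errors),
        success_auc=float(scurve.mean()),
        precision_thresholds=pth.tolist(),
        precision_curve=pcurve.tolist(),
        success_thresholds=sth.tolist(),
        success_curve=scurve.tolist(),
    )
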