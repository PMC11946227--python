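"""Keypoint-localization error and grade-classification accuracy."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, ValidationError
from .keypoint_io import KEYPOINTS, GradeLabel, TrajectoryBout


@dataclass(frozen=True)
class KeypointErrorReport:
    """Mean Euclidean distance (pixels) between predicted and true keypoints.

    ``global_mean_px`` is the unweighted mean of the per-keypoint means
    (each keypoint type contributes equally, regardless of how many of
    its frames were comparable), not a pooled mean over all points.
    """

    per_keypoint_mean_px: dict[str, float]
    global_mean_px: float
    n_points: int


@dataclass(frozen=True)
class AccuracyReport:
    confusion: np.ndarray  # 4x4 counts, rows = true grade, cols = predicted
    per_grade_accuracy: dict[int, float]
    overall_accuracy: float


def keypoint_error(pred: TrajectoryBout, truth: TrajectoryBout) -> KeypointErrorReport:
    """Per-keypoint and global mean Euclidean distance, in pixels.

    Only frames present in both bouts are compared; frames missing in
    either bout are excluded pairwise per keypoint.
    """
    common = pred.data.index.intersection(truth.data.index)
    if len(common) == 0:
        raise InsufficientDataError("no overlapping frames between pred and truth")
    per_kp = {}
    n_points = 0
    for kp in KEYPOINTS:
        p = pred.data.loc[common, kp][["x", "y"]].to_numpy(float)
        t = truth.data.loc[common, kp][["x", "y"]].to_numpy(float)
        ok = np.isfinite(p).all(axis=1) & np.isfinite(t).all(axis=1)
        if not ok.any():
            continue
        d = np.sqrt(np.sum((p[ok] - t[ok]) ** 2, axis=1))
        per_kp[kp] = float(d.mean())
        n_points += int(ok.sum())
    if not per_kp:
        raise InsufficientDataError("no comparable keypoint observations")
    return KeypointErrorReport(
        per_keypoint_mean_px=per_kp,
        global_mean_px=float(np.mean(list(per_kp.values()))),
        n_points=n_points,
    )


def grade_accuracy(
    predictions: list[tuple[str, int]], labels: list[GradeLabel]
) -> AccuracyReport:
    """Confusion matrix and accuracies of predicted vs true grades.

    ``per_grade_accuracy[g]`` is the diagonal count over the row total
    for true grade ``g`` (NaN for grades absent from the labels);
    ``overall_accuracy`` is trace over total.
    """
    by_id = {l.bout_id: l.grade for l in labels}
    confusion = np.zeros((4, 4), dtype=int)
    unmatched = [bid for bid, _ in predictions if bid not in by_id]
    if unmatched:
        raise ValidationError(
            f"predictions without a matching label: {', '.join(sorted(unmatched))}"
        )
    if not predictions:
        raise InsufficientDataError("no predictions to evaluate")
    for bid, pred_grade in predictions:
        if pred_grade not in (0, 1, 2, 3):
            raise ValidationError(f"predicted grade {pred_grade!r} outside 0..3")
        confusion[by_id[bid], pred_grade] += 1
    row_totals = confusion.sum(axis=1)
    per_grade = {
        g: (confusion[g, g] / row_totals[g] if row_totals[g] else float("nan"))
        for g in range(4)
    }
    return AccuracyReport(
        confusion=confusion,
        per_grade_accuracy=per_grade,
        overall_accuracy=float(np.trace(confusion) / confusion.sum()),
    )


def confusion_frame(report: AccuracyReport) -> pd.DataFrame:
    """Confusion matrix as a labelled DataFrame (for reports/stdout)."""
    return pd.DataFrame(
        report.confusion,
        index=[f"true_{g}" for g in range(4)],
        columns=[f"pred_{g}" for g in range(4)],
    )
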