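"""Trajectory cleaning and feature-triangle angle extraction.

Two triangles are built from the four tracked keypoints of a walking
cow.  The first has its vertex at K2 (back, near the neck) with K1
(head) and K4 (tail) as base endpoints; its vertex angle is called
``alpha``.  The second has its vertex at K3 (mid back) with K2 and K4
as base endpoints; its vertex angle is ``beta``.  A sound cow walks
with a straight back and a steady head, so both angles stay large
(alpha roughly 146-165 degrees, beta above 175 degrees) and vary
little.  Lameness produces an arched back and head bobbing, which
depresses the angles and widens their variation — the signal the
scoring model consumes.

Angles are computed with the law of cosines at the triangle vertex and
reported in degrees.  Because the angles depend only on ratios of
inter-keypoint distances, they are invariant to translation, rotation,
reflection and uniform scaling of the image — in particular to the
distance between the cow and the camera.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, ValidationError
from .keypoint_io import KEYPOINTS, TrajectoryBout

#: Default likelihood below which a detection is treated as unreliable.
DEFAULT_LIKELIHOOD_THRESHOLD = 0.6
#: Longest run of unreliable frames bridged by interpolation (~0.5 s at 25 fps).
DEFAULT_MAX_GAP = 12
#: Fewest valid frames (~2 s at 25 fps) for which a summary is produced.
DEFAULT_MIN_VALID_FRAMES = 50


@dataclass
class AngleSeries:
    """Per-frame feature-triangle angles, in degrees; NaN marks missing."""

    bout_id: str
    fps: float
    frame_index: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        self.frame_index = np.asarray(self.frame_index)
        self.alpha = np.asarray(self.alpha, float)
        self.beta = np.asarray(self.beta, float)
        if not (len(self.frame_index) == len(self.alpha) == len(self.beta)):
            raise ValidationError("frame_index, alpha and beta must align")
        for name, arr in (("alpha", self.alpha), ("beta", self.beta)):
            present = arr[np.isfinite(arr)]
            if present.size and (present.min() <= 0 or present.max() > 180):
                raise ValidationError(f"{name} values must lie in (0, 180]")

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame_index": self.frame_index, "alpha": self.alpha, "beta": self.beta}
        )

    def to_csv(self, path: str | Path) -> Path:
        """Export as ``frame_index,alpha,beta`` CSV (for plotting etc.)."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.10g")
        return path

    @classmethod
    def from_csv(cls, path: str | Path, fps: float, bout_id: str | None = None):
        path = Path(path)
        df = pd.read_csv(path)
        return cls(
            bout_id or path.stem,
            fps,
            df["frame_index"].to_numpy(int),
            df["alpha"].to_numpy(float),
            df["beta"].to_numpy(float),
        )


@dataclass(frozen=True)
class AngleSummary:
    """Variation interval, mean and amplitude of one angle over a bout."""

    interval_low: float
    interval_high: float
    mean: float
    amplitude: float
    n_valid_frames: int


@dataclass(frozen=True)
class GaitSummary:
    bout_id: str
    alpha: AngleSummary
    beta: AngleSummary


def keypoint_distance(a, b):
    """Euclidean distance between two keypoints, in pixels.

    Accepts single points or (n, 2) arrays; missing coordinates yield
    NaN results.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = a - b
    return np.sqrt(np.sum(d * d, axis=-1))


def vertex_angle(vertex, end1, end2):
    """Angle at ``vertex`` of the triangle (end1, vertex, end2), in degrees.

    Computed with the law of cosines from the three side lengths:
    ``arccos((b^2 + c^2 - a^2) / (2 b c))`` where ``b`` and ``c`` are the
    vertex-to-endpoint distances and ``a`` the base.  The cosine argument
    is clamped to [-1, 1] before arccos so collinear configurations map
    exactly to 180 (or 0) degrees.  Degenerate triangles — a
    vertex-to-endpoint distance of zero — yield NaN.

    Accepts single points or (n, 2) arrays.
    """
    b = keypoint_distance(vertex, end1)
    c = keypoint_distance(vertex, end2)
    a = keypoint_distance(end1, end2)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = (b * b + c * c - a * a) / (2.0 * b * c)
        cos = np.clip(cos, -1.0, 1.0)
        ang = np.degrees(np.arccos(cos))
        ang = np.where((b > 0) & (c > 0), ang, np.nan)
    if ang.ndim == 0:
        return float(ang)
    return ang


def clean_trajectory(
    bout: TrajectoryBout,
    likelihood_threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD,
    max_gap: int = DEFAULT_MAX_GAP,
) -> TrajectoryBout:
    """Replace low-likelihood detections by linear interpolation.

    Frames with likelihood below ``likelihood_threshold`` have their
    coordinates replaced by linear interpolation between the nearest
    reliable frames, but only across runs of at most ``max_gap``
    consecutive bad frames; longer gaps, and leading/trailing bad
    frames (which would require extrapolation), remain flagged missing.

    Motivated by the neck keypoint K2, whose detections fluctuate the
    most in practice.
    """
    df = bout.data.copy()
    pos = df.index.to_numpy(float)  # interpolate in frame-index time
    for kp in KEYPOINTS:
        like = df[(kp, "likelihood")].to_numpy(float)
        coords = df[kp][["x", "y"]].to_numpy(float)
        bad = (like < likelihood_threshold) | ~np.isfinite(coords).all(axis=1)
        if not bad.any():
            continue
        good = ~bad
        filled = coords.copy()
        filled[bad] = np.nan
        # locate runs of bad frames bounded by good frames on both sides
        n = len(bad)
        i = 0
        while i < n:
            if not bad[i]:
                i += 1
                continue
            j = i
            while j < n and bad[j]:
                j += 1
            run = j - i
            if i > 0 and j < n and run <= max_gap and good[i - 1] and good[j]:
                t0, t1 = pos[i - 1], pos[j]
                w = (pos[i:j] - t0) / (t1 - t0)
                for axis in range(2):
                    filled[i:j, axis] = (1 - w) * coords[i - 1, axis] + w * coords[
                        j, axis
                    ]
            i = j
        df[(kp, "x")] = filled[:, 0]
        df[(kp, "y")] = filled[:, 1]
        newlike = like.copy()
        still_missing = ~np.isfinite(filled).all(axis=1)
        newlike[still_missing] = 0.0
        df[(kp, "likelihood")] = newlike
    return TrajectoryBout(bout.bout_id, bout.fps, df)


def compute_angle_series(bout: TrajectoryBout) -> AngleSeries:
    """Compute the per-frame feature-triangle angles alpha and beta.

    ``alpha[t]`` is the vertex angle at K2 of triangle (K1, K2, K4);
    ``beta[t]`` the vertex angle at K3 of triangle (K2, K3, K4).  Frames
    where any required keypoint is missing yield a missing angle; the
    two angles have independent dependency sets (alpha needs K1/K2/K4,
    beta needs K2/K3/K4).
    """
    k1, k2, k3, k4 = (bout.xy(kp) for kp in KEYPOINTS)
    alpha = vertex_angle(k2, k1, k4)
    beta = vertex_angle(k3, k2, k4)
    # exact collinearity can produce angle 0 for a folded triangle;
    # fold-through never occurs for real cows, treat it as missing
    alpha = np.where(alpha > 0, alpha, np.nan)
    beta = np.where(beta > 0, beta, np.nan)
    return AngleSeries(bout.bout_id, bout.fps, bout.frame_index, alpha, beta)


def _summarize_one(
    values: np.ndarray,
    name: str,
    interval_method: str,
    percentile_tail: float,
    min_valid_frames: int,
) -> AngleSummary:
    present = values[np.isfinite(values)]
    if present.size < min_valid_frames:
        raise InsufficientDataError(
            f"angle {name}: {present.size} valid frames, "
            f"need at least {min_valid_frames}"
        )
    if interval_method == "minmax":
        low, high = float(present.min()), float(present.max())
    elif interval_method == "percentile":
        low, high = (
            float(x)
            for x in np.percentile(present, [percentile_tail, 100 - percentile_tail])
        )
    else:
        raise ValueError(f"unknown interval_method {interval_method!r}")
    return AngleSummary(
        interval_low=low,
        interval_high=high,
        mean=float(present.mean()),
        amplitude=high - low,
        n_valid_frames=int(present.size),
    )


def summarize_angles(
    series: AngleSeries,
    interval_method: str = "minmax",
    percentile_tail: float = 2.5,
    min_valid_frames: int = DEFAULT_MIN_VALID_FRAMES,
) -> GaitSummary:
    """Per-bout variation interval, mean and amplitude of each angle.

    The variation interval is the min/max of the present values
    (``interval_method="minmax"``) or the (tail, 100-tail) percentile
    range (``"percentile"``, robust to single-frame artifacts).  The
    amplitude is defined as the interval width ``high - low``.

    Raises
    ------
    InsufficientDataError
        If either angle has fewer than ``min_valid_frames`` valid frames.
    """
    return GaitSummary(
        bout_id=series.bout_id,
        alpha=_summarize_one(
            series.alpha, "alpha", interval_method, percentile_tail, min_valid_frames
        ),
        beta=_summarize_one(
            series.beta, "beta", interval_method, percentile_tail, min_valid_frames
        ),
    )
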