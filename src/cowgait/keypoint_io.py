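"""Reading and writing keypoint trajectory tables and grade-label files.

The pipeline consumes pose-tracker output for four keypoints along the
cow's head-to-tail axis: K1 (mouth/head), K2 (back, near the neck),
K3 (mid back) and K4 (back, near the tail).  Two table dialects are
supported:

* the DeepLabCut-style CSV with three header rows (scorer / bodyparts /
  coords) and one leading frame-index column, and
* a plain long format with columns ``frame,keypoint,x,y,likelihood``.

Coordinates are image coordinates: origin top-left, y increasing
downward, units pixels.  Cells that are empty or non-finite are kept as
flagged-missing entries (NaN coordinates, likelihood 0) rather than
dropped, so frame indexing stays aligned with video time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .exceptions import FormatError, MissingKeypointError, ValidationError

#: Keypoint names, ordered head to tail.
KEYPOINTS = ("K1", "K2", "K3", "K4")

#: Per-keypoint sub-columns, in DLC order.
COORDS = ("x", "y", "likelihood")

#: Frame rate of the recording setup the defaults were derived from.
DEFAULT_FPS = 25.0

_SCORER = "cowgait"


@dataclass(frozen=True)
class FrameRecord:
    """Keypoint observations for a single video frame."""

    frame_index: int
    x: dict[str, float]
    y: dict[str, float]
    likelihood: dict[str, float]


@dataclass(frozen=True)
class GradeLabel:
    """Ground-truth lameness grade (0 normal .. 3 severe) for one bout."""

    bout_id: str
    grade: int

    def __post_init__(self):
        if self.grade not in (0, 1, 2, 3):
            raise ValidationError(
                f"grade must be one of 0,1,2,3; got {self.grade!r} "
                f"for bout {self.bout_id!r}"
            )


@dataclass
class TrajectoryBout:
    """Time-indexed keypoint positions and likelihoods for one walking bout.

    ``data`` holds one row per frame, indexed by frame number, with a
    two-level column index ``(keypoint, coord)`` where coord is ``x``,
    ``y`` or ``likelihood``.  Missing observations are NaN coordinates
    with likelihood 0.
    """

    bout_id: str
    fps: float
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if not self.fps > 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        cols = [(kp, c) for kp in KEYPOINTS for c in COORDS]
        missing = sorted({kp for kp, c in cols if (kp, c) not in self.data.columns})
        if missing:
            raise MissingKeypointError(missing)
        self.data = self.data.loc[:, cols]
        idx = self.data.index.to_numpy()
        if len(idx) > 1 and not np.all(np.diff(idx) > 0):
            raise ValidationError("frame indices must be strictly increasing")
        like = self.data.loc[:, (slice(None), "likelihood")].to_numpy(float)
        if like.size and (np.nanmin(like) < 0 or np.nanmax(like) > 1):
            raise ValidationError("likelihood values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def frame_index(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def xy(self, keypoint: str) -> np.ndarray:
        """(n_frames, 2) array of pixel coordinates for one keypoint."""
        return self.data[keypoint][["x", "y"]].to_numpy(float)

    def likelihood(self, keypoint: str) -> np.ndarray:
        return self.data[(keypoint, "likelihood")].to_numpy(float)

    def frames(self) -> Iterator[FrameRecord]:
        for idx, row in self.data.iterrows():
            yield FrameRecord(
                frame_index=int(idx),
                x={kp: float(row[(kp, "x")]) for kp in KEYPOINTS},
                y={kp: float(row[(kp, "y")]) for kp in KEYPOINTS},
                likelihood={kp: float(row[(kp, "likelihood")]) for kp in KEYPOINTS},
            )

    def copy(self) -> "TrajectoryBout":
        return TrajectoryBout(self.bout_id, self.fps, self.data.copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrajectoryBout):
            return NotImplemented
        if self.bout_id != other.bout_id or self.fps != other.fps:
            return False
        if self.data.shape != other.data.shape:
            return False
        if not self.data.index.equals(other.data.index):
            return False
        a = self.data.to_numpy(float)
        b = other.data.to_numpy(float)
        return bool(np.allclose(a, b, rtol=0, atol=1e-9, equal_nan=True))


def bout_from_arrays(
    bout_id: str,
    fps: float,
    coords: dict[str, np.ndarray],
    likelihoods: dict[str, np.ndarray] | None = None,
    frame_index: np.ndarray | None = None,
) -> TrajectoryBout:
    """Assemble a :class:`TrajectoryBout` from per-keypoint (n, 2) arrays."""
    n = len(next(iter(coords.values())))
    if frame_index is None:
        frame_index = np.arange(n)
    blocks = {}
    for kp in KEYPOINTS:
        xy = np.asarray(coords[kp], float)
        like = (
            np.ones(n) if likelihoods is None else np.asarray(likelihoods[kp], float)
        )
        like = np.where(np.isfinite(xy).all(axis=1), like, 0.0)
        blocks[(kp, "x")] = xy[:, 0]
        blocks[(kp, "y")] = xy[:, 1]
        blocks[(kp, "likelihood")] = like
    df = pd.DataFrame(blocks, index=np.asarray(frame_index))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["bodyparts", "coords"])
    return TrajectoryBout(bout_id, fps, df)


def _normalize_missing(df: pd.DataFrame) -> pd.DataFrame:
    """Flag rows with non-finite coordinates: keep NaN, force likelihood 0."""
    for kp in KEYPOINTS:
        bad = ~(
            np.isfinite(df[(kp, "x")].to_numpy(float))
            & np.isfinite(df[(kp, "y")].to_numpy(float))
        )
        like = df[(kp, "likelihood")].to_numpy(float)
        like = np.where(np.isfinite(like), like, 0.0)
        like[bad] = 0.0
        df[(kp, "likelihood")] = like
    return df


def read_dlc_table(
    path: str | Path,
    fps: float = DEFAULT_FPS,
    bout_id: str | None = None,
    dialect: str = "dlc",
) -> TrajectoryBout:
    """Read a keypoint trajectory table.

    Parameters
    ----------
    path:
        CSV file in the DLC three-header-row dialect (``dialect="dlc"``)
        or the long format ``frame,keypoint,x,y,likelihood``
        (``dialect="long"``).
    fps:
        Frame rate of the recording; the table dialects do not carry it.
    bout_id:
        Identifier for the bout; defaults to the file stem.
    """
    path = Path(path)
    if bout_id is None:
        bout_id = path.stem
    if dialect == "long":
        return _read_long_table(path, fps, bout_id)
    if dialect != "dlc":
        raise ValueError(f"unknown dialect {dialect!r}")

    try:
        raw = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (pd.errors.ParserError, ValueError, IndexError) as exc:
        raise FormatError(f"{path}: cannot parse three-row DLC header: {exc}") from exc
    for col in raw.columns:
        if len(col) != 3 or col[2] not in COORDS:
            raise FormatError(
                f"{path}: malformed header at column {'/'.join(map(str, col))}; "
                f"third header row must be one of {COORDS}"
            )
    # Drop the scorer level; keep (bodypart, coord).
    raw.columns = pd.MultiIndex.from_tuples(
        [(bp, c) for _, bp, c in raw.columns], names=["bodyparts", "coords"]
    )
    present = set(raw.columns.get_level_values(0))
    missing = [kp for kp in KEYPOINTS if kp not in present]
    if missing:
        raise MissingKeypointError(missing)
    df = raw.loc[:, [(kp, c) for kp in KEYPOINTS for c in COORDS]].astype(float)
    try:
        df.index = df.index.astype(int)
    except (TypeError, ValueError):
        df.index = pd.RangeIndex(len(df))
    df = _normalize_missing(df)
    return TrajectoryBout(bout_id, fps, df)


def _read_long_table(path: Path, fps: float, bout_id: str) -> TrajectoryBout:
    raw = pd.read_csv(path)
    required = {"frame", "keypoint", "x", "y", "likelihood"}
    if not required.issubset(raw.columns):
        raise FormatError(
            f"{path}: long format requires columns {sorted(required)}, "
            f"found {list(raw.columns)}"
        )
    missing = [kp for kp in KEYPOINTS if kp not in set(raw["keypoint"])]
    if missing:
        raise MissingKeypointError(missing)
    wide = raw.pivot(index="frame", columns="keypoint", values=["x", "y", "likelihood"])
    df = pd.DataFrame(index=wide.index)
    for kp in KEYPOINTS:
        for c in COORDS:
            df[(kp, c)] = wide[(c, kp)].astype(float)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["bodyparts", "coords"])
    df.index = df.index.astype(int)
    df = _normalize_missing(df)
    return TrajectoryBout(bout_id, fps, df)


def write_dlc_table(bout: TrajectoryBout, path: str | Path) -> Path:
    """Write a bout as a DLC-dialect CSV readable by :func:`read_dlc_table`.

    Numeric fields are serialized with enough significant digits for a
    value-identical round trip.
    """
    path = Path(path)
    out = bout.data.copy()
    out.columns = pd.MultiIndex.from_tuples(
        [(_SCORER, kp, c) for kp, c in out.columns],
        names=["scorer", "bodyparts", "coords"],
    )
    out.to_csv(path, float_format="%.17g")
    return path


def read_labels(path: str | Path) -> list[GradeLabel]:
    """Read a two-column ``bout_id,grade`` CSV of ground-truth grades."""
    path = Path(path)
    raw = pd.read_csv(path, dtype={"bout_id": str})
    if not {"bout_id", "grade"}.issubset(raw.columns):
        raise FormatError(
            f"{path}: label file requires columns bout_id,grade; "
            f"found {list(raw.columns)}"
        )
    labels = []
    for pos, row in enumerate(raw.itertuples(index=False)):
        try:
            grade = int(row.grade)
            if grade != float(row.grade):
                raise ValueError
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}: row {pos + 2}: grade {row.grade!r} is not an integer"
            ) from None
        try:
            labels.append(GradeLabel(str(row.bout_id), grade))
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {pos + 2}: {exc}") from None
    return labels


def write_labels(labels: list[GradeLabel], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"bout_id": [l.bout_id for l in labels], "grade": [l.grade for l in labels]}
    ).to_csv(path, index=False)
    return path
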