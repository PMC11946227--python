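"""Banded lameness scoring against a normal-cow reference.

The model compares how a bout's feature angles are distributed relative
to the variation interval of sound (grade-0) cows.  For each angle an
overlap coefficient in [0, 1] is formed — by default the fraction of
the bout's per-frame values falling inside the normal reference
interval (``sample_fraction``), alternatively the proportional overlap
of the bout's own variation interval with the reference
(``interval_overlap``).  Each coefficient is mapped to an initial score
through fixed bands:

====================  =====================
score                 C_alpha       C_beta
====================  =====================
0 (normal)            [0.75, 1]     [0.90, 1]
1 (mild)              [0.50, 0.75)  [0.80, 0.90)
2 (moderate)          [0.25, 0.50)  [0.70, 0.80)
3 (severe)            [0, 0.25)     [0, 0.70)
====================  =====================

The final score is the ceiling of the mean of the two initial scores,
``S = ceil((S_alpha + S_beta) / 2)``, mapped to the four-level grade
scale normal / mild / moderate / severe.  Shared band endpoints are
closed on the better-score side (benefit of the doubt at ties).

:class:`LamenessScorer` packages the model as a scikit-learn style
classifier whose ``fit`` can calibrate the reference interval from
bouts of known-sound cows of a new herd; the default reference is the
interval observed for the 45-cow herd the model was developed on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import gait_features as gf
from .exceptions import InsufficientDataError, ValidationError
from .keypoint_io import TrajectoryBout

#: Normal-cow (grade 0) variation interval of alpha, degrees.
NORMAL_ALPHA_INTERVAL = (146.26, 164.87)
#: Normal-cow (grade 0) variation interval of beta, degrees.
NORMAL_BETA_INTERVAL = (175.29, 179.99)
#: Lower band edges for S_alpha = 0, 1, 2 (3 below the last edge).
ALPHA_BAND_EDGES = (0.75, 0.50, 0.25)
#: Lower band edges for S_beta = 0, 1, 2 (3 below the last edge).
BETA_BAND_EDGES = (0.90, 0.80, 0.70)
#: Grade labels by final score.
GRADE_LABELS = ("normal", "mild", "moderate", "severe")


def _check_interval(low, high, name):
    if not (np.isfinite(low) and np.isfinite(high) and low < high):
        raise ValidationError(f"{name} reference interval must satisfy low < high")


def _check_edges(edges, name):
    edges = tuple(float(e) for e in edges)
    if len(edges) != 3 or not all(0 < e < 1 for e in edges):
        raise ValidationError(f"{name} band edges must be three values in (0, 1)")
    if not (edges[0] > edges[1] > edges[2]):
        raise ValidationError(f"{name} band edges must be strictly decreasing")
    return edges


@dataclass(frozen=True)
class ReferenceModel:
    """Normal-cow reference intervals plus the score-band edges."""

    alpha_ref_low: float = NORMAL_ALPHA_INTERVAL[0]
    alpha_ref_high: float = NORMAL_ALPHA_INTERVAL[1]
    beta_ref_low: float = NORMAL_BETA_INTERVAL[0]
    beta_ref_high: float = NORMAL_BETA_INTERVAL[1]
    alpha_bands: tuple = ALPHA_BAND_EDGES
    beta_bands: tuple = BETA_BAND_EDGES
    overlap_method: str = "sample_fraction"

    def __post_init__(self):
        _check_interval(self.alpha_ref_low, self.alpha_ref_high, "alpha")
        _check_interval(self.beta_ref_low, self.beta_ref_high, "beta")
        object.__setattr__(self, "alpha_bands", _check_edges(self.alpha_bands, "alpha"))
        object.__setattr__(self, "beta_bands", _check_edges(self.beta_bands, "beta"))
        if self.overlap_method not in ("sample_fraction", "interval_overlap"):
            raise ValidationError(
                f"unknown overlap_method {self.overlap_method!r}"
            )


@dataclass(frozen=True)
class OverlapCoefficients:
    c_alpha: float
    c_beta: float


@dataclass(frozen=True)
class LamenessScore:
    s_alpha: int
    s_beta: int
    s_final: int
    grade_label: str


@dataclass(frozen=True)
class BoutScore:
    """Full audit trail for one scored bout."""

    bout_id: str
    coefficients: OverlapCoefficients
    score: LamenessScore
    summary: gf.GaitSummary = field(repr=False)


def overlap_coefficient(
    values,
    ref_low: float,
    ref_high: float,
    method: str = "sample_fraction",
    test_interval: tuple[float, float] | None = None,
) -> float:
    """Degree of overlap between a bout's angle values and a reference.

    ``sample_fraction``: the fraction of present per-frame values lying
    inside ``[ref_low, ref_high]`` — frame-weighted and robust to single
    outlier frames.  ``interval_overlap``: ``|test ∩ ref| / |test|``
    where ``test`` is the bout's own variation interval (supplied via
    ``test_interval`` or taken as min/max of ``values``); 0 if disjoint,
    1 if the test interval is contained in the reference.
    """
    _check_interval(ref_low, ref_high, "overlap")
    if method == "sample_fraction":
        values = np.asarray(values, float)
        present = values[np.isfinite(values)]
        if present.size == 0:
            raise InsufficientDataError("no valid angle values for overlap")
        frac = np.mean((present >= ref_low) & (present <= ref_high))
        return float(np.clip(frac, 0.0, 1.0))
    if method == "interval_overlap":
        if test_interval is None:
            values = np.asarray(values, float)
            present = values[np.isfinite(values)]
            if present.size == 0:
                raise InsufficientDataError("no valid angle values for overlap")
            test_interval = (float(present.min()), float(present.max()))
        lo, hi = test_interval
        if hi <= lo:  # zero-width interval: inside or outside the reference
            return 1.0 if ref_low <= lo <= ref_high else 0.0
        inter = min(hi, ref_high) - max(lo, ref_low)
        return float(np.clip(max(inter, 0.0) / (hi - lo), 0.0, 1.0))
    raise ValueError(f"unknown overlap method {method!r}")


def _band_score(c: float, edges: tuple[float, float, float]) -> int:
    if not (0.0 <= c <= 1.0):
        raise ValidationError(f"overlap coefficient must lie in [0, 1], got {c}")
    for score, edge in enumerate(edges):
        if c >= edge:
            return score
    return 3


def score_alpha(c_alpha: float, bands: tuple = ALPHA_BAND_EDGES) -> int:
    """Initial score for angle alpha from its overlap coefficient."""
    return _band_score(c_alpha, _check_edges(bands, "alpha"))


def score_beta(c_beta: float, bands: tuple = BETA_BAND_EDGES) -> int:
    """Initial score for angle beta from its overlap coefficient."""
    return _band_score(c_beta, _check_edges(bands, "beta"))


def final_score(s_alpha: int, s_beta: int) -> LamenessScore:
    """Combine the two initial scores: ``S = ceil((S_alpha + S_beta)/2)``.

    Decimal averages are rounded up to the nearest whole number, which
    only affects odd sums.
    """
    for name, s in (("s_alpha", s_alpha), ("s_beta", s_beta)):
        if s not in (0, 1, 2, 3):
            raise ValidationError(f"{name} must be in 0..3, got {s!r}")
    s = math.ceil((s_alpha + s_beta) / 2)
    return LamenessScore(
        s_alpha=int(s_alpha),
        s_beta=int(s_beta),
        s_final=int(s),
        grade_label=GRADE_LABELS[s],
    )


class LamenessScorer(ClassifierMixin, BaseEstimator):
    """Lameness grading of walking bouts, as a scikit-learn classifier.

    ``fit`` establishes the normal-cow reference intervals: either the
    configured/default intervals, or — when fitted on bouts of
    known-sound cows — the pooled variation interval of those bouts
    (per-herd calibration).  ``predict`` maps bouts to grades 0-3.

    Parameters
    ----------
    alpha_ref, beta_ref:
        Reference intervals ``(low, high)`` in degrees, or None to use
        the built-in normal-cow defaults (or to calibrate from ``X`` in
        ``fit``).
    alpha_band_edges, beta_band_edges:
        Descending lower band edges for initial scores 0, 1 and 2.
    overlap_method:
        ``"sample_fraction"`` (default) or ``"interval_overlap"``.
    likelihood_threshold, max_gap:
        Trajectory-cleaning options, see
        :func:`cowgait.gait_features.clean_trajectory`.
    min_valid_frames:
        Fewest valid frames per angle for a bout to be scorable.
    interval_method, percentile_tail:
        How a bout's variation interval is formed, see
        :func:`cowgait.gait_features.summarize_angles`.
    """

    def __init__(
        self,
        alpha_ref=None,
        beta_ref=None,
        alpha_band_edges=ALPHA_BAND_EDGES,
        beta_band_edges=BETA_BAND_EDGES,
        overlap_method="sample_fraction",
        likelihood_threshold=gf.DEFAULT_LIKELIHOOD_THRESHOLD,
        max_gap=gf.DEFAULT_MAX_GAP,
        min_valid_frames=gf.DEFAULT_MIN_VALID_FRAMES,
        interval_method="minmax",
        percentile_tail=2.5,
    ):
        self.alpha_ref = alpha_ref
        self.beta_ref = beta_ref
        self.alpha_band_edges = alpha_band_edges
        self.beta_band_edges = beta_band_edges
        self.overlap_method = overlap_method
        self.likelihood_threshold = likelihood_threshold
        self.max_gap = max_gap
        self.min_valid_frames = min_valid_frames
        self.interval_method = interval_method
        self.percentile_tail = percentile_tail

    # -- internal helpers -------------------------------------------------
    def _angles(self, item) -> gf.AngleSeries:
        if isinstance(item, gf.AngleSeries):
            return item
        if isinstance(item, TrajectoryBout):
            cleaned = gf.clean_trajectory(
                item, self.likelihood_threshold, self.max_gap
            )
            return gf.compute_angle_series(cleaned)
        raise TypeError(
            f"expected TrajectoryBout or AngleSeries, got {type(item).__name__}"
        )

    def _calibrate_interval(self, values: np.ndarray, name: str):
        present = values[np.isfinite(values)]
        if present.size < self.min_valid_frames:
            raise InsufficientDataError(
                f"reference calibration for {name}: {present.size} valid frames, "
                f"need at least {self.min_valid_frames}"
            )
        if self.interval_method == "percentile":
            lo, hi = np.percentile(
                present, [self.percentile_tail, 100 - self.percentile_tail]
            )
        else:
            lo, hi = present.min(), present.max()
        return float(lo), float(hi)

    # -- scikit-learn API --------------------------------------------------
    def fit(self, X=None, y=None):
        """Fix the reference model.

        ``X`` may be None/empty (use configured or default reference
        intervals) or an iterable of normal-cow bouts / angle series
        whose pooled variation interval becomes the reference.
        """
        alpha_ref = self.alpha_ref
        beta_ref = self.beta_ref
        if (alpha_ref is None or beta_ref is None) and X:
            series = [self._angles(item) for item in X]
            alpha_pool = np.concatenate([s.alpha for s in series])
            beta_pool = np.concatenate([s.beta for s in series])
            if alpha_ref is None:
                alpha_ref = self._calibrate_interval(alpha_pool, "alpha")
            if beta_ref is None:
                beta_ref = self._calibrate_interval(beta_pool, "beta")
        if alpha_ref is None:
            alpha_ref = NORMAL_ALPHA_INTERVAL
        if beta_ref is None:
            beta_ref = NORMAL_BETA_INTERVAL
        self.reference_ = ReferenceModel(
            alpha_ref_low=float(alpha_ref[0]),
            alpha_ref_high=float(alpha_ref[1]),
            beta_ref_low=float(beta_ref[0]),
            beta_ref_high=float(beta_ref[1]),
            alpha_bands=tuple(self.alpha_band_edges),
            beta_bands=tuple(self.beta_band_edges),
            overlap_method=self.overlap_method,
        )
        self.classes_ = np.arange(4)
        return self

    def _ensure_fitted(self):
        if not hasattr(self, "reference_"):
            self.fit()

    def score_bout(self, bout) -> BoutScore:
        """Score one bout (or angle series), returning all intermediates."""
        self._ensure_fitted()
        ref = self.reference_
        series = self._angles(bout)
        try:
            summary = gf.summarize_angles(
                series,
                interval_method=self.interval_method,
                percentile_tail=self.percentile_tail,
                min_valid_frames=self.min_valid_frames,
            )
        except InsufficientDataError as exc:
            raise InsufficientDataError(f"bout {series.bout_id!r}: {exc}") from None
        c_alpha = overlap_coefficient(
            series.alpha,
            ref.alpha_ref_low,
            ref.alpha_ref_high,
            method=ref.overlap_method,
            test_interval=(summary.alpha.interval_low, summary.alpha.interval_high),
        )
        c_beta = overlap_coefficient(
            series.beta,
            ref.beta_ref_low,
            ref.beta_ref_high,
            method=ref.overlap_method,
            test_interval=(summary.beta.interval_low, summary.beta.interval_high),
        )
        s_a = _band_score(c_alpha, ref.alpha_bands)
        s_b = _band_score(c_beta, ref.beta_bands)
        return BoutScore(
            bout_id=series.bout_id,
            coefficients=OverlapCoefficients(c_alpha=c_alpha, c_beta=c_beta),
            score=final_score(s_a, s_b),
            summary=summary,
        )

    def predict(self, X) -> np.ndarray:
        """Final lameness score (0-3) for each bout in ``X``."""
        self._ensure_fitted()
        return np.array([self.score_bout(b).score.s_final for b in X])

    def predict_details(self, X) -> pd.DataFrame:
        """Per-bout score report with all intermediates.

        Columns: bout_id, c_alpha, c_beta, s_alpha, s_beta, s_final,
        grade_label, n_valid_frames (minimum over the two angles).
        """
        self._ensure_fitted()
        rows = []
        for b in X:
            r = self.score_bout(b)
            rows.append(
                {
                    "bout_id": r.bout_id,
                    "c_alpha": r.coefficients.c_alpha,
                    "c_beta": r.coefficients.c_beta,
                    "s_alpha": r.score.s_alpha,
                    "s_beta": r.score.s_beta,
                    "s_final": r.score.s_final,
                    "grade_label": r.score.grade_label,
                    "n_valid_frames": min(
                        r.summary.alpha.n_valid_frames, r.summary.beta.n_valid_frames
                    ),
                }
            )
        return pd.DataFrame(rows)


def score_bout(
    bout,
    reference: ReferenceModel | None = None,
    **options,
) -> BoutScore:
    """Score a single bout against a reference model (module-level helper).

    ``options`` are forwarded to :class:`LamenessScorer`.
    """
    if reference is not None:
        options.setdefault(
            "alpha_ref", (reference.alpha_ref_low, reference.alpha_ref_high)
        )
        options.setdefault(
            "beta_ref", (reference.beta_ref_low, reference.beta_ref_high)
        )
        options.setdefault("alpha_band_edges", reference.alpha_bands)
        options.setdefault("beta_band_edges", reference.beta_bands)
        options.setdefault("overlap_method", reference.overlap_method)
    return LamenessScorer(**options).fit().score_bout(bout)
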