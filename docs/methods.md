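# Methods

## The scoring model

A walking bout is a single traversal of the camera's field of view by one cow
(about 6 s at 25 fps in the recording setup the defaults come from). Per
frame, the tracker supplies pixel coordinates and a detection likelihood for
four landmarks K1–K4 along the head-to-tail axis. The pipeline is a fixed
composition:

1. **Cleaning.** Detections with likelihood below 0.6 are treated as missing;
   runs of up to `max_gap = 12` consecutive missing frames (~0.5 s) are
   bridged by linear interpolation per coordinate. Longer gaps and
   leading/trailing runs stay missing — no extrapolation. Both thresholds are
   configurable; they are engineering defaults (the neck keypoint K2 is the
   jitter-prone one in practice), not measured constants.
2. **Angles.** α(t) is the vertex angle at K2 in triangle (K1, K2, K4), β(t)
   the vertex angle at K3 in (K2, K3, K4), via the law of cosines with the
   cosine argument clamped to [−1, 1]. Frames missing any required keypoint
   yield a missing angle; α and β have different dependency sets and fail
   independently. Angles are in degrees and invariant under similarity
   transforms of the image, which is what makes the method indifferent to
   camera distance and cow size.
3. **Summary.** Each angle's variation interval over the bout is its min/max
   (`minmax`, the default) or a percentile range (`percentile`, robust to
   single-frame artifacts such as a cow licking a railing, which drives α
   briefly out of band). The amplitude is defined as the interval width. A
   bout needs at least `min_valid_frames = 50` valid frames (~2 s) per angle
   to be scorable; below that an insufficient-data error names the angle.
4. **Overlap.** The overlap coefficient of an angle against the normal-cow
   reference interval is, by default, the fraction of present frames inside
   the reference (`sample_fraction`) — frame-weighted, bounded in [0, 1], and
   insensitive to a few artifact frames. The alternative `interval_overlap`
   is |test ∩ ref| / |test| on the variation intervals; it reproduces the
   interval-based reading of the model but inherits the min/max's artifact
   sensitivity. Both are implemented; the choice is logged in every run.
5. **Banding and combination.** Sα: 0 for Cα ∈ [0.75, 1], 1 for [0.50, 0.75),
   2 for [0.25, 0.50), 3 for [0, 0.25). Sβ: 0 for [0.90, 1], 1 for
   [0.80, 0.90), 2 for [0.70, 0.80), 3 for [0, 0.70). Shared band endpoints
   are closed on the better-score side (benefit of the doubt at ties; the
   boundary convention is covered by tests). Final score
   S = ⌈(Sα + Sβ)/2⌉, so a half-integer mean rounds toward the worse grade;
   S maps to normal / mild / moderate / severe.

The default reference intervals (α 146.26–164.87°, β 175.29–179.99°) are the
sound-cow variation intervals of the 45-cow herd the model was developed on.
They are config-overridable, and `LamenessScorer.fit(sound_bouts)` calibrates
them from known-sound bouts of a new herd (pooled min/max or percentile
interval of the cleaned angle values).

One cell of the published per-grade amplitude table is internally
inconsistent: the severe-β interval 162.99–179.95° implies a width of 16.96°,
but the printed amplitude is 17.96°. The package computes 16.96 from the
endpoints and treats the printed value as a typo.

## The simulator

The generator works backwards from the measured quantity. It first draws
target angle series with grade-dependent statistics, then solves for
keypoint positions realizing those angles exactly, then corrupts the
coordinates. This ordering gives every downstream stage a known ground
truth.

**Angle dynamics.** Each angle follows

```
x(t) = mean + half_range · env(t) · sin(2π f t + φ) + jitter,
```

clipped to `mean ± half_range`, with stride frequency f = 1.5 Hz, a random
phase per bout, and Gaussian jitter (sd 0.25°). `env(t)` is a triangular
amplitude envelope with period 3 s: stride amplitude waxes and wanes, so
over a 6 s bout the amplitude multiplier sweeps [0, 1] with a uniform time
distribution. This envelope is the load-bearing modelling choice. A
constant-amplitude sinusoid spends most of its time at its extremes
(arcsine stationary distribution), which contradicts the published per-grade
statistics in two places: a mildly lame cow's β interval dips 1.76° below
the normal band, yet mild cows must spend ≥ 80% of frames inside it (a
bout's interval is set by its extremes, not by where it dwells); and a
severely lame cow's α mean sits only 0.36° below the normal band's lower
edge, yet severe cows must keep Cα < 0.50. With the triangular envelope the
stationary distribution concentrates near the per-cow mean while bout
extremes still reach the full variation interval, and the per-grade overlap
coefficients land mid-band: grade 0 → (Cα, Cβ) ≈ (1.00, 1.00), grade 1 ≈
(0.82, 0.84), grade 2 ≈ (0.80, 0.57), grade 3 ≈ (0.46, 0.17), mapping to
final scores 0/1/2/3. The stride frequency 1.5 Hz was chosen so a 6 s bout
holds exactly 9 stride cycles and 2 envelope periods, making the per-bout
sample fractions phase-insensitive (over all phases, severe-α Cα stays in
[0.427, 0.460], clear of the 0.50 band edge). `amplitude_mod="none"`
restores the plain sinusoid. None of this is a biomechanical claim; it is
the simplest waveform whose within-bout distribution is consistent with the
grade statistics it must emulate.

**Per-grade defaults.** Means and variation intervals per grade are the
published herd statistics (e.g. grade 0 α mean 156.2779°, interval
146.26–164.87°; grade 3 α mean 145.9024°, interval 133.34–156.27°). The
half-range defaults to the largest symmetric range around the mean that
stays inside the printed interval, so generated bouts respect the interval
by construction.

**Geometry.** K1 and K4 advance left-to-right on a horizontal baseline
(walk speed 2 px/frame) with K1–K4 separation 3 × spacing (spacing 400 px,
i.e. a cow spanning ~1200 px — a side-view animal filling most of a
1080p/4K frame). K2 is placed above the baseline at one third of the base
from K1, its height solved by bisection so the vertex angle equals α(t) to
1e-9°; K3 is solved the same way above the midpoint of the (slanted) K2–K4
segment for β(t). With zero noise the full
synthesize → realize → re-extract round trip errs by < 1e-6° per frame.
Targets of exactly 180° are rejected (degenerate collinear triangle).

**Corruption.** Gaussian coordinate noise (sd `noise_sd`, "moderate" = 2 px
at this geometry, ≈ 0.3° of angle noise) is added after solving; dropout
frames (probability `dropout_rate`) get likelihood 0.1 and grossly perturbed
coordinates, exercising the cleaning stage; the `railing_lick` artifact
displaces K1 up and forward for a contiguous 10% of frames, reproducing the
known failure mode where a cow licking a railing drives α out of band.

**Cohorts.** `simulate_cohort` draws n bouts per grade, reproducibly from a
base seed. By default each cow also receives an individual offset on both
angle means (sd 1.5°), emulating individual differences among cows. Note
the tension this creates: with mean jitter on, a severe cow whose α mean
drifts +0.4° crosses the normal band's lower edge and its bout legitimately
bands as moderate — individual variation blurs the grade boundaries exactly
as it would in a real herd. The recovery guarantees below therefore hold
for cohorts at exact grade-default parameters (`mean_jitter_sd=0`).

## What the tests do and do not show

On simulated cohorts at grade-default parameters with 2 px noise and 2%
dropout (25 bouts per grade), scoring recovers 100% of grade-0 and grade-3
bouts and ≥ 90% overall — by construction: sound bouts' angle supports lie
fully inside the normal band and severe bouts' substantially outside, and
the envelope analysis above was checked before the assertions were written.
This demonstrates that the implementation of the scoring arithmetic,
geometry and simulator is self-consistent; it does not demonstrate field
accuracy. Real tracking error is structured (occlusion, railing confusions,
per-keypoint bias), real gait is not a two-tone sinusoid, and real grade
boundaries are contested even between human scorers. Published field
accuracy for this model family (~90% overall) was measured on real video
with a trained tracker and is not reproducible from synthetic data.

## Numerical choices

- Cosine clamped to [−1, 1] before arccos; collinear points give exactly
  180°; a zero-length triangle arm gives a missing angle, not an exception.
- Bisection: bracket expanded geometrically until it contains the target,
  then up to 200 halvings or until the achieved angle is within 1e-9°;
  generation fails loudly if the solver leaves > 1e-6° residual.
- Overlap coefficients clamped to [0, 1]; a zero-width test interval counts
  as fully inside the reference iff its point lies inside.
- Interpolation is linear in frame-index time, per coordinate, per keypoint;
  likelihoods of interpolated frames keep their original (sub-threshold)
  values so the provenance of reconstructed frames remains visible.
- DLC tables are written with 17 significant digits for exact value
  round-trips; the three-row header (scorer/bodyparts/coords) matches the
  tracker-output dialect.
- Seeds: every stochastic component takes an explicit seed; cohort child
  seeds derive from the base seed via `numpy.random.SeedSequence`.

## Known limitations

- One cow per bout; no multi-animal disambiguation.
- No stride segmentation, hoof tracking, gait speed or cadence features;
  the score uses only the two angles.
- The sample-fraction overlap treats frames as exchangeable; it ignores the
  temporal pattern of excursions (a limp every stride and one long artifact
  excursion can produce the same coefficient — use `percentile` summaries
  and the audit columns to tell them apart).
- Reference intervals are herd-specific; scoring a new herd against the
  bundled defaults without calibration is a known source of bias.
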