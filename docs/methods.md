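# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `gazecmp`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## Signal model and conventions

A gaze trace is a uniformly sampled monocular stream of horizontal/vertical
eye position in degrees of visual angle with a per-sample validity flag.
Binocular recording is out of scope: the analyses operate on a single gaze
signal per trial, which is how the downstream metrics are defined anyway.
All units are degrees and seconds inside the library; the I/O layer is the
only place where anything else may appear.

* **Differentiation** is by central differences on interior samples and
  one-sided differences at the ends, with no pre-smoothing by default — the
  detector thresholds are defined on raw velocity. An optional
  Savitzky–Golay smoother (odd window length in samples, polynomial order 2
  by default) can be applied to the positions before differentiation.
  A velocity sample is valid only if every position sample under its stencil
  is valid; the acceleration (derivative of the Euclidean speed) shares that
  mask rather than propagating a second, wider stencil — one invalid sample
  therefore poisons exactly its three-sample neighborhood.
* **Intervals** (events, exclusion windows) are closed in time. Sample
  membership is decided by timestamp with a 1 ns tolerance so grid points
  that land exactly on a boundary are included regardless of floating-point
  representation.
* **Resampling** is linear interpolation onto a new uniform grid spanning
  the same time range; a resampled sample is valid only if both bracketing
  source samples are valid.

## Target paradigms

Three trial generators reproduce a standard oculomotor battery:

* **Saccade task** (4 s): 1 s central fixation, step to one of eight targets
  45° apart at 10° eccentricity (seeded-random balanced order), 2 s hold,
  step back, 1 s hold.
* **Step-ramp pursuit** (4 s): 1 s fixation, step to 10° in one of the four
  cardinal directions, constant centripetal motion at 10 °/s for 2 s (the
  target crosses the center and ends at the mirror position), 1 s fixation.
* **Circular pursuit** (≈5.93 s): 1 s fixation, step to a random phase on a
  5°-radius circle, clockwise motion at a tangential speed of 10 °/s for 5/4
  orbits (5π/4 ≈ 3.93 s), step back, 1 s fixation.

Ramp speed and orbit radius are exact to 1e-6 by construction; the tests
verify this and the finite-difference tangential speed.

## The eye simulator

The simulator builds an ideal (noise-free) eye path and then layers
measurement artifacts on top. Its defaults are the study conditions; they
were chosen once, from standard oculomotor values, and are not tuned.

**Saccades** use the minimum-jerk displacement profile
`s(τ) = 10τ³ − 15τ⁴ + 6τ⁵` — smooth, differentiable, and with the
closed-form peak velocity `1.875·A/D` that the tests exploit. Durations
follow a main-sequence model `D(ms) = 2.2·A(deg) + 21`, giving ≈43 ms and a
≈436 °/s peak for a 10° saccade, inside the 390–470 °/s band typical for
that amplitude. Primary saccades (responses to a target step, latency
200 ± 30 ms truncated at 80 ms) undershoot by 10% of the step. Secondary
saccades are triggered whenever the position error exceeds a threshold
(0.75° during fixation, 1.0° during pursuit, 100 ms refractory period after
any saccade) and close the full remaining error; this makes the eye converge
on the target, so an injected calibration offset is recoverable from the
fixation mean, while still producing the ~1° corrective/catch-up saccades
whose detection separates the two rules. No secondary saccade is scheduled
in response to a target step that an already-pending primary will handle.

**Pursuit** moves the eye at `gain × target velocity` between saccades, so
the steady-state eye speed is exactly `gain × 10 °/s` in the noise-free
case; with gain < 1 the accumulating position error generates realistic
catch-up saccades.

**Artifacts**: white Gaussian position noise (default SD 0.05°, a realistic
video-tracker precision), a constant drift velocity drawn per fixation
period (SD 0.05 °/s), blinks as Poisson validity-loss events (0.1 /s,
uniform 100–300 ms), and finally an additive **calibration-offset field** —
a quadratic polynomial in true gaze position per output axis. The field is a
configurable stand-in for the spatially systematic accuracy errors of
video-based trackers (e.g. larger errors in one vertical hemifield, with
opposite sign patterns for different camera geometries); it makes no claim
about their physical cause. The offset is evaluated at the true eye
position, mirroring the fact that the subject sees the target veridically
while only the measurement is displaced.

Every injected event and parameter is recorded in a `GroundTruth` object.
Identical seeds give bit-identical traces. A trajectory rendered at 500 Hz
and resampled to 230 Hz matches a direct 230 Hz rendering up to event-timing
quantization (reactive events quantize at both their trigger and their own
onset, hence up to two sample periods) and 0.05° in amplitude.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real recordings: head movement and its compensation,
pupil-size artifacts, asymmetric/skewed saccade velocity profiles, dynamic
overshoot, saccadic oscillations, tracker-specific filtering, and
non-stationary calibration drift (slippage). In particular, real saccades
are not minimum-jerk; see "Known limitations".

## Event detection

Both detectors use strict inequality at their thresholds (ties break toward
non-saccade), operate only on valid samples (invalid samples split runs),
and take event boundaries at the supra-threshold samples themselves with no
sub-sample interpolation — whether real device parsers interpolate is not
inferable from their outputs, so the simpler convention is fixed and
documented. The liberal rule's two criteria are OR-combined by default
(AND is available). No minimum inter-saccade merge interval is applied by
default; a merge gap is configurable.

Event summaries: amplitude is the Euclidean onset-to-offset displacement,
duration the sample span (a single-sample event has zero duration), mean and
peak velocity are taken over the event's speed samples, and direction is the
atan2 angle of the displacement.

Blinks are maximal invalid runs longer than 20 ms; the exclusion window
spans 40 ms before onset to 60 ms after offset, clipped to the trace and
merged when overlapping.

In the composed pipeline the liberal detector runs on lightly smoothed
velocity (Savitzky–Golay, 22 ms window): its 30 °/s threshold lies inside
the raw central-difference noise floor of a trace with 0.05° position noise
(≈17 °/s per axis at 500 Hz), which would otherwise saturate it — the same
reason real laboratory parsers filter before detecting. The conservative
run rule is applied to raw velocity; robustness to that noise floor is
precisely its design rationale.

## Fixation analysis

Fixation periods are delimited by detected saccades with amplitude strictly
greater than 7°; each period runs from a delimiting saccade's offset plus
one sample (so saccade samples never bias the mean) to the next delimiter's
onset. Corrective saccades at or below 7° remain inside the period and are
deliberately included in the mean, as are drift samples; blink-masked
samples are excluded (mask-aware averaging). Trials whose outward or return
saccade was not detected (e.g. a blink split the saccade's sample run) are
flagged and excluded from aggregation, and the pipeline reconciles counts
(simulated = analyzed + flagged). The absolute fixation error is the
Euclidean distance between the target and the mean eye position; aggregation
averages within subject and position first, then reports across-subject
mean ± SD per position plus the across-position average.

A "relative fixation error" is sometimes reported alongside the absolute
one in comparison studies without a standard definition; it is not
implemented here.

## Pursuit analysis

The steady-state window opens 300 ms after the offset of the initial saccade
toward the pursuit target (anchoring at the offset, not the onset, because
the settling rule is meant to skip pursuit initiation after landing) and
closes at the end of the pursuit segment minus half the gain-smoother
support (50 ms), so the velocity estimate never straddles the segment
boundary. If no initial saccade is found the window anchors at pursuit onset
and the trial is flagged. Catch-up saccades are excluded with the same
40/60 ms padding as blinks. Trials with less than 200 ms of kept data are
dropped and counted.

Gain is the mean instantaneous Euclidean eye speed over the kept samples
divided by the target speed — mean speed, not displacement-over-time or a
regression slope, because the Euclidean-speed combination is exactly what
makes circular-pursuit gain exceed 1.0 under noise (Jensen's inequality:
`E|g·vt + ε| ≥ g·|vt|`, equality iff ε ≡ 0). Velocity for gain estimation
uses a 100 ms Savitzky–Golay estimate; at 0.05° position noise this brings
the per-axis velocity noise to ≈0.24 °/s, making the Jensen inflation of the
gain itself ≈3e-4 — negligible against the ±0.02 recovery target, while the
detectors keep running on their own signal.

**Component gains** for circular pursuit are the through-origin
least-squares slopes of eye on target component velocity over the kept
samples. An RMS-amplitude ratio was considered and rejected: for a sinusoid
of RMS amplitude `r` with per-axis noise σ, the RMS ratio inflates by
≈σ²/(2·g·r²) per unit — about twice the Euclidean-speed inflation at these
parameters — which would invert the documented ordering (overall Euclidean
gain ≥ component gains). The regression slope is unbiased under zero-mean
noise, so the ordering holds with equality exactly in the noise-free case.

Parameter-recovery experiments analyze with the liberal detector: ~1°
catch-up saccades peak below 100 °/s, so the conservative rule cannot see —
and therefore cannot exclude — them, biasing recovered gain upward by
≈+0.14 at a true gain of 0.8. That bias is itself a finding about
high-threshold detectors (it reappears as the higher circular gain of the
"esc-like" system in the full pipeline), not a defect of the estimator, but
recovery experiments are supposed to isolate the estimator. The recovery
experiments simulate with the stated position noise only (no drift, no
blinks) so that the quantity being recovered is well defined.

## Statistics

* Inter-individual SD: per-subject per-condition trial means → SD across
  subjects per condition (n−1) → average across conditions. The verbal
  definition this implements is ambiguous in common usage ("the SD of these
  averages for each subject"); the reading used here is the only one that
  measures between-subject heterogeneity, which is what the quantity is
  for. Intra-individual SD: per-cell SD across trials → average across
  conditions within subject → grand mean across subjects; cells with fewer
  than two trials are dropped with a warning.
* One-way repeated-measures ANOVA by the classical partition
  `SS_total = SS_treatment + SS_subjects + SS_error`,
  `F = MS_treatment/MS_error` on `(k−1, (k−1)(n−1))` df; for two levels this
  equals the squared paired t. The two-way fully-within interaction F is
  tested against its interaction-by-subject residual. Sums of squares below
  1e-12 of the total are treated as exact zeros so that additive (zero
  interaction) and identical-column tables return F = 0, p = 1 instead of a
  ratio of rounding noise. No sphericity correction is applied by default;
  Greenhouse–Geisser ε is available for the one-way test. The
  implementation is a direct sums-of-squares computation; the test suite
  cross-checks it against `statsmodels` `AnovaRM` and the paired t against
  `scipy.stats.ttest_rel`.
* All SDs use the n−1 denominator. Both decompositions are
  translation-invariant and absolutely homogeneous (property-tested).

## Cohort simulation

The synthetic comparison cohort gives every subject a per-system
calibration-offset field: a central offset with random direction and
magnitude `|N(0.45°, 0.12°)|` for the laboratory-style ("elii-like", 500 Hz)
system versus `|N(1.20°, 0.50°)|` for the mobile-style ("esc-like", 230 Hz)
system, plus a linear vertical field term of opposite mean sign per system
(0.004 ± 0.002 vs −0.012 ± 0.006 per degree) emulating opposite
hemifield-asymmetric error patterns. These magnitudes sit in the range of
published accuracy figures for the two classes of tracker. Because only the
between-subject offset variance differs, the cohort reproduces the
characteristic variability structure — inter-individual SD much larger for
the mobile-style system, intra-individual SDs nearly equal — which the
acceptance suite checks on 8 subjects × 8 positions × 3 trials per system
(a desk-scale design; the per-cell trial count keeps individual SD
estimates noisy, which the averaging over 64 cells absorbs).

## Problem sizes and determinism

The test suite and acceptance script run entirely on synthetic data at the
paradigms' native rates: detector oracle checks on 1,000 random sequences,
recovery experiments on 20 trials per condition at 500 Hz, Monte-Carlo
Jensen checks on 100 draws of 8 s of circular tracking, and the cohort
above; the whole suite completes in well under a minute. Every random
quantity flows from an explicit integer seed through
`numpy.random.Generator`; identical seeds give identical outputs, including
across the CLI.

## Known limitations

* Minimum-jerk saccades are symmetric and overshoot-free; real saccades are
  skewed and often show dynamic overshoot. One measurable consequence: with
  supra-threshold-only event boundaries, the conservative rule's amplitude
  for a clean 10° minimum-jerk saccade is ≈4–5.5% smaller than the liberal
  rule's (the sub-100 °/s flanks carry ≈4% of the displacement, plus up to
  ≈1% boundary discretization at 500 Hz), whereas comparisons on real data
  report sub-3% amplitude differences — real waveforms concentrate less
  displacement in the flanks, and overshoot can even flip the sign of the
  difference.
* The calibration-offset field is static per trial; tracker slippage and
  drift-correction dynamics are not modeled.
* Blink kinematics (lid-occlusion artifacts in the position signal just
  before/after the validity loss) are not simulated; blinks are pure
  validity loss.
* Clock alignment between stimulus and tracker timelines is reduced to a
  single per-trial offset in the file metadata; trials without an alignment
  record are excluded rather than re-synchronized.
* Microsaccades, pupil-size analysis, the vestibulo-ocular reflex and
  binocular vergence are out of scope.
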