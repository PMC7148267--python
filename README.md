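# gazecmp

Eye-movement analysis for quantitative eye-tracker comparison studies.

When the same gaze recording is analyzed with different eye-trackers'
standard detection rules, the reported saccade parameters can differ even
though the underlying eye movement is identical. `gazecmp` re-implements the
full analysis pipeline used to compare a mobile-style and a laboratory-style
video eye-tracker on the three classic oculomotor paradigms — visually
guided saccades with fixation periods, step-ramp (Rashbass) linear pursuit,
and circular pursuit — together with a synthetic eye-trace generator with
exact ground truth, so that every stage is testable without any recorded
data.

## Who it is for

Oculomotor and eye-tracking-methodology researchers who want to

* run the two standard saccade-detection rules side by side and quantify how
  the choice of rule changes amplitude, duration, and mean velocity;
* compute absolute fixation error and smooth-pursuit velocity gain with the
  standard steady-state and artifact-exclusion conventions;
* decompose measurement variability into between-subject (calibration
  quality) and within-subject (trial-to-trial) components;
* validate an analysis chain against simulated data with known ground truth.

## The methods at the core

**Saccade detectors.** Two velocity-threshold rules on the Euclidean speed
`s = sqrt(vx² + vy²)` of the differentiated gaze signal:

* *run rule* (conservative, mobile-tracker style): a saccade is a maximal run
  of valid samples with `s > 100 °/s` lasting at least 3 samples;
* *velocity-or-acceleration rule* (liberal, laboratory-tracker style): a
  sample is saccadic if `s > 30 °/s` or `|ds/dt| > 8000 °/s²`.

Because the conservative rule keeps only the fast core of a saccade, the same
movement gets a shorter duration, slightly smaller amplitude and a higher
mean velocity; saccades of ~1° (peak < 100 °/s) are missed entirely.

**Blink exclusion.** Blinks are runs of lost signal; all samples from 40 ms
before to 60 ms after a blink are masked.

**Fixation accuracy.** Fixation periods are delimited by saccades with
amplitude > 7°; the absolute fixation error of a target is
`|mean(eye) − target|` over the period (small corrective saccades and drift
included).

**Pursuit gain.** `gain = mean Euclidean eye speed / target speed` over
steady-state pursuit (starting 300 ms after the initial saccade lands),
with segments from 40 ms before to 60 ms after every catch-up saccade
excluded. For circular pursuit, per-axis component gains are also estimated
(regression slope of eye on target component velocity); zero-mean velocity
noise inflates the Euclidean-speed gain but not the component slopes, which
is how circular gain can exceed 1.0 while both components stay below it.

**Variability statistics.** Inter-individual SD (average the trials per
subject and condition, SD across subjects per condition, average over
conditions) versus intra-individual SD (SD across trials per cell, averaged
within then across subjects); one-way repeated-measures ANOVA
(`F = MS_treatment/MS_error`, for two levels `F = t²` of the paired t), the
two-way fully-within interaction F, and the paired t test.

## Worked example

```python
import numpy as np
from gazecmp import compute_velocity, detect_saccades_run, detect_saccades_vel_acc
from gazecmp.simulate import make_two_saccade_trace
from gazecmp.pipeline import pursuit_gain_experiment

trace, truth = make_two_saccade_trace(rate=500.0)   # 10 deg + 1 deg saccade
vel = compute_velocity(trace)
for name, events in [("run rule (100 deg/s, 3 samples)", detect_saccades_run(trace, vel)),
                     ("velocity-or-acceleration rule", detect_saccades_vel_acc(trace, vel))]:
    print(f"{name}: {len(events)} saccade(s)")
    for e in events:
        print(f"  amp {e.amplitude:5.2f} deg  dur {e.duration_ms:4.1f} ms  "
              f"mean {e.mean_velocity:5.1f} deg/s  peak {e.peak_velocity:5.1f} deg/s")

gains = pursuit_gain_experiment(true_gain=0.9, n_trials=20, rate=500.0, seed=1)
print(f"recovered pursuit gain: {np.mean(gains):.3f} (true 0.90, n={len(gains)})")
```

prints

```
run rule (100 deg/s, 3 samples): 1 saccade(s)
  amp  9.45 deg  dur 30.0 ms  mean 300.8 deg/s  peak 433.1 deg/s
velocity-or-acceleration rule: 2 saccade(s)
  amp  9.99 deg  dur 40.0 ms  mean 238.0 deg/s  peak 433.1 deg/s
  amp  0.94 deg  dur 16.0 ms  mean  53.6 deg/s  peak  78.8 deg/s
recovered pursuit gain: 0.902 (true 0.90, n=20)
```

The same physical 10° saccade is 30 ms long with a 300 °/s mean velocity
under the conservative rule but 40 ms and 238 °/s under the liberal one
(identical peak velocity), and only the liberal rule sees the 1° corrective
saccade — the detector, not the eye, makes the difference. The recovered
pursuit gain shows the analysis chain is unbiased to within a few thousandths
when catch-up saccades are properly excluded.

## Command line

```sh
gazecmp simulate --paradigm saccade --rate 500 --trials 8 --seed 1 --out traces/
gazecmp detect --detector esc --in traces/ --out events.json
gazecmp analyze fixation --traces traces/ --out fixation.tsv
gazecmp analyze pursuit  --traces traces/ --out pursuit.tsv
gazecmp stats --metrics fixation.tsv --test sd-decomp --out stats.tsv
gazecmp run --seed 1 --out results/
```

Traces are plain CSV (`time_s,x_deg,y_deg,valid`) with a JSON metadata
sidecar; all outputs are TSV/JSON.

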