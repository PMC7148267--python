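"""Saccade and blink detection.

Two velocity-threshold saccade detectors are implemented, modeled on the
default analysis rules of two classes of video-based eye-trackers:

* the **run rule** (robust, mobile-tracker style): a saccade is a maximal run
  of consecutive valid samples whose speed exceeds 100 deg/s for at least
  three successive data points;
* the **velocity-or-acceleration rule** (liberal, laboratory-tracker style):
  a sample is saccadic if its speed exceeds 30 deg/s or the magnitude of its
  acceleration exceeds 8,000 deg/s^2; events are maximal runs of saccadic
  valid samples with no minimum run length.

Both rules use strict inequality at the threshold (ties break toward
non-saccade), and event boundaries are the supra-threshold samples themselves
(no sub-sample interpolation).  Runs containing invalid samples are split.
The conservative run rule keeps fewer low-velocity samples at the flanks of a
saccade, so the same physical saccade gets a shorter duration, a slightly
smaller amplitude, and a higher mean velocity than under the liberal rule --
and small (~1 deg) corrective saccades whose peak velocity stays below
100 deg/s are missed entirely.

Blinks are runs of invalid samples longer than a configurable minimum; the
standard artifact exclusion masks all data from 40 ms before until 60 ms
after each blink.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trace import EyeTrace, VelocityTrace, merge_windows

RULE_VELOCITY_RUN = "velocity_run"
RULE_VEL_ACC = "velocity_or_acceleration"


@dataclass
class SaccadeEvent:
    """A detected saccade with its kinematic summary.

    ``amplitude`` is the Euclidean displacement from onset to offset sample,
    ``duration_ms`` the time between them, ``direction_deg`` the atan2 angle
    of the displacement, and mean/peak velocity are taken over the event's
    speed samples.
    """

    onset_t: float
    offset_t: float
    onset_i: int
    offset_i: int
    duration_ms: float
    amplitude: float
    mean_velocity: float
    peak_velocity: float
    direction_deg: float

    def to_dict(self, detector: str | None = None) -> dict:
        d = {
            "type": "saccade",
            "onset_s": self.onset_t,
            "offset_s": self.offset_t,
            "amplitude_deg": self.amplitude,
            "duration_ms": self.duration_ms,
            "mean_vel_dps": self.mean_velocity,
            "peak_vel_dps": self.peak_velocity,
            "direction_deg": self.direction_deg,
        }
        if detector:
            d["detector"] = detector
        return d


@dataclass
class BlinkEvent:
    onset_t: float
    offset_t: float

    def to_dict(self) -> dict:
        return {"type": "blink", "onset_s": self.onset_t, "offset_s": self.offset_t}


@dataclass
class DetectorConfig:
    """Saccade-detector rule and thresholds.

    ``combine`` selects whether the velocity and acceleration criteria of the
    liberal rule are OR-ed (default, matching the device-manual behavior the
    rule is modeled on) or AND-ed.  ``merge_gap_s`` optionally merges events
    separated by less than the given gap (off by default).
    """

    rule: str = RULE_VELOCITY_RUN
    v_threshold: float = 100.0   # deg/s
    min_run: int = 3             # samples
    a_threshold: float | None = None  # deg/s^2
    combine: str = "or"
    merge_gap_s: float = 0.0

    def __post_init__(self) -> None:
        if self.v_threshold <= 0:
            raise ValueError("v_threshold must be positive")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.rule not in (RULE_VELOCITY_RUN, RULE_VEL_ACC):
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.combine not in ("or", "and"):
            raise ValueError("combine must be 'or' or 'and'")


def esc_detector_config() -> DetectorConfig:
    """The conservative run rule: speed > 100 deg/s for >= 3 samples."""
    return DetectorConfig(rule=RULE_VELOCITY_RUN, v_threshold=100.0, min_run=3)


def elii_detector_config() -> DetectorConfig:
    """The liberal rule: speed > 30 deg/s or |accel| > 8000 deg/s^2."""
    return DetectorConfig(rule=RULE_VEL_ACC, v_threshold=30.0, min_run=1,
                          a_threshold=8000.0)


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array, as inclusive (start, stop)."""
    if mask.size == 0:
        return []
    m = mask.astype(np.int8)
    d = np.diff(np.concatenate(([0], m, [0])))
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0] - 1
    return list(zip(starts.tolist(), stops.tolist()))


def summarize_saccade(
    trace: EyeTrace, vel: VelocityTrace, onset_i: int, offset_i: int
) -> SaccadeEvent:
    """Kinematic summary of a saccadic sample run.

    Amplitude is the onset-to-offset Euclidean displacement; duration is the
    sample span in ms; mean and peak velocity are taken over the event's
    speed samples.  A single-sample event has zero duration and mean == peak.
    """
    if onset_i > offset_i:
        raise ValueError(f"onset index {onset_i} after offset index {offset_i}")
    sl = slice(onset_i, offset_i + 1)
    if not np.all(trace.valid[sl]):
        bad = onset_i + int(np.argmin(trace.valid[sl]))
        raise ValueError(
            f"invalid sample {bad} inside saccade [{onset_i}, {offset_i}]"
        )
    dx = trace.x[offset_i] - trace.x[onset_i]
    dy = trace.y[offset_i] - trace.y[onset_i]
    speeds = vel.speed[sl]
    return SaccadeEvent(
        onset_t=float(trace.time[onset_i]),
        offset_t=float(trace.time[offset_i]),
        onset_i=int(onset_i),
        offset_i=int(offset_i),
        duration_ms=1000.0 * (offset_i - onset_i) / trace.rate,
        amplitude=float(math.hypot(dx, dy)),
        mean_velocity=float(np.mean(speeds)),
        peak_velocity=float(np.max(speeds)),
        direction_deg=float(math.degrees(math.atan2(dy, dx))),
    )


def _merge_runs(
    runs: list[tuple[int, int]], gap_samples: int
) -> list[tuple[int, int]]:
    if gap_samples <= 0 or not runs:
        return runs
    merged = [runs[0]]
    for a, b in runs[1:]:
        if a - merged[-1][1] - 1 < gap_samples:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return merged


def _detect(
    trace: EyeTrace, vel: VelocityTrace, mask: np.ndarray, config: DetectorConfig
) -> list[SaccadeEvent]:
    runs = [r for r in _mask_runs(mask) if r[1] - r[0] + 1 >= config.min_run]
    runs = _merge_runs(runs, int(round(config.merge_gap_s * trace.rate)))
    return [summarize_saccade(trace, vel, a, b) for a, b in runs]


def detect_saccades_run(
    trace: EyeTrace, vel: VelocityTrace, config: DetectorConfig | None = None
) -> list[SaccadeEvent]:
    """Run-rule saccade detection (speed > threshold for >= min_run samples)."""
    config = config or esc_detector_config()
    if config.rule != RULE_VELOCITY_RUN:
        raise ValueError(f"config rule is {config.rule!r}, expected velocity_run")
    if vel.n == 0:
        return []
    mask = vel.valid & (vel.speed > config.v_threshold)
    return _detect(trace, vel, mask, config)


def detect_saccades_vel_acc(
    trace: EyeTrace, vel: VelocityTrace, config: DetectorConfig | None = None
) -> list[SaccadeEvent]:
    """Velocity-or-acceleration saccade detection."""
    config = config or elii_detector_config()
    if config.rule != RULE_VEL_ACC:
        raise ValueError(
            f"config rule is {config.rule!r}, expected velocity_or_acceleration"
        )
    if config.a_threshold is None:
        raise ValueError("velocity_or_acceleration rule needs a_threshold")
    if vel.n == 0:
        return []
    v_crit = vel.speed > config.v_threshold
    a_crit = np.abs(vel.accel) > config.a_threshold
    crit = (v_crit | a_crit) if config.combine == "or" else (v_crit & a_crit)
    mask = vel.valid & crit
    return _detect(trace, vel, mask, config)


def detect_saccades(
    trace: EyeTrace, vel: VelocityTrace, config: DetectorConfig
) -> list[SaccadeEvent]:
    """Dispatch on the configured detector rule."""
    if config.rule == RULE_VELOCITY_RUN:
        return detect_saccades_run(trace, vel, config)
    return detect_saccades_vel_acc(trace, vel, config)


def detect_blinks(trace: EyeTrace, min_duration_s: float = 0.020) -> list[BlinkEvent]:
    """Blinks as maximal invalid-sample runs longer than ``min_duration_s``."""
    out = []
    for a, b in _mask_runs(~trace.valid):
        if (b - a) / trace.rate > min_duration_s:
            out.append(BlinkEvent(float(trace.time[a]), float(trace.time[b])))
    return out


def blink_exclusion_windows(
    blinks: Sequence[BlinkEvent],
    t_range: tuple[float, float] | None = None,
    pre_s: float = 0.040,
    post_s: float = 0.060,
) -> list[tuple[float, float]]:
    """Artifact-exclusion windows around blinks.

    Each window spans from ``pre_s`` before blink onset to ``post_s`` after
    blink offset (defaults 40 and 60 ms), clipped to ``t_range`` when given;
    overlapping windows are merged.
    """
    ws = []
    for b in blinks:
        a, z = b.onset_t - pre_s, b.offset_t + post_s
        if t_range is not None:
            a, z = max(a, t_range[0]), min(z, t_range[1])
        ws.append((a, z))
    return merge_windows(ws)


__all__ = [
    "SaccadeEvent",
    "BlinkEvent",
    "DetectorConfig",
    "esc_detector_config",
    "elii_detector_config",
    "detect_saccades_run",
    "detect_saccades_vel_acc",
    "detect_saccades",
    "detect_blinks",
    "blink_exclusion_windows",
    "summarize_saccade",
    "RULE_VELOCITY_RUN",
    "RULE_VEL_ACC",
]
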