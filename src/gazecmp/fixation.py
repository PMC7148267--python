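"""Fixation segmentation and absolute fixation-error estimation.

In the saccade task, fixation and saccade periods alternate.  A fixation
period on a target begins after the large (amplitude > 7 deg) saccade toward
that target and ends at the onset of the next large saccade; small corrective
saccades and drift inside the period are deliberately included in the average
eye position.  The absolute fixation error for a target is the Euclidean
distance between the target position and the mean (mask-aware) eye position
during its fixation period -- an accuracy measure, as opposed to the
sample-to-sample precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import SaccadeEvent
from .simulate import Segment, TargetTrajectory
from .trace import EyeTrace, TIME_EPS

log = logging.getLogger(__name__)

#: saccades larger than this amplitude (deg) delimit fixation periods
DELIMITER_AMPLITUDE = 7.0


@dataclass
class FixationPeriod:
    """A fixation interval with its target and mean eye position."""

    start_t: float
    end_t: float
    target: tuple[float, float]
    position: str
    mean_eye: tuple[float, float]
    n_valid: int
    flagged: bool = False


def segment_fixations(
    trace: EyeTrace,
    saccades: Sequence[SaccadeEvent],
    schedule: Sequence[Segment],
    min_amplitude: float = DELIMITER_AMPLITUDE,
) -> list[FixationPeriod]:
    """Split a trial into fixation periods delimited by large saccades.

    Only saccades with amplitude strictly greater than ``min_amplitude``
    delimit periods; each period runs from one delimiting saccade's offset
    (plus one sample, so saccade samples never bias the mean) to the next
    one's onset, with the trial start/end bounding the first/last period.
    Each period is assigned the scheduled fixation target containing its
    midpoint; periods without a scheduled target (e.g. during pursuit) are
    dropped.  If no delimiting saccade is found, only the initial central
    fixation is emitted, flagged.
    """
    big = sorted(
        (s for s in saccades if s.amplitude > min_amplitude),
        key=lambda s: s.onset_t,
    )
    dt = trace.dt
    fix_sched = [s for s in schedule if s.label == "fixation"]
    flagged = not big
    if flagged:
        # no delimiting saccade: only the initial central fixation is usable
        if not fix_sched:
            return []
        bounds = [(fix_sched[0].t0, fix_sched[0].t1)]
    else:
        starts = [trace.time[0]] + [s.offset_t + dt for s in big]
        ends = [s.onset_t for s in big] + [trace.time[-1]]
        bounds = list(zip(starts, ends))

    fix_segs = fix_sched
    out: list[FixationPeriod] = []
    for a, b in bounds:
        if b - a <= dt:
            continue
        mid = 0.5 * (a + b)
        seg = next(
            (s for s in fix_segs if s.t0 - TIME_EPS <= mid < s.t1 - TIME_EPS
             or (s is fix_segs[-1] and mid <= s.t1 + TIME_EPS)),
            None,
        )
        if seg is None:
            continue
        sel = (trace.time >= a - TIME_EPS) & (trace.time <= b + TIME_EPS) & trace.valid
        n_valid = int(np.count_nonzero(sel))
        if n_valid == 0:
            log.warning("fixation period [%.3f, %.3f] has no valid samples; dropped",
                        a, b)
            continue
        out.append(FixationPeriod(
            start_t=float(a), end_t=float(b),
            target=tuple(seg.params["target"]),
            position=str(seg.params["position"]),
            mean_eye=(float(trace.x[sel].mean()), float(trace.y[sel].mean())),
            n_valid=n_valid,
            flagged=flagged,
        ))
        if flagged:
            break  # only the central fixation is trustworthy
    return out


def absolute_fixation_error(fix: FixationPeriod) -> float:
    """Euclidean distance between target and mean eye position, in degrees."""
    return math.hypot(
        fix.mean_eye[0] - fix.target[0], fix.mean_eye[1] - fix.target[1]
    )


def fixation_errors_for_trial(
    trace: EyeTrace,
    saccades: Sequence[SaccadeEvent],
    trajectory: TargetTrajectory,
    min_amplitude: float = DELIMITER_AMPLITUDE,
) -> list[dict]:
    """Per-position absolute fixation errors of one saccade-task trial.

    Returns one record per fixation period with keys ``position``,
    ``error_deg``, ``n_valid`` and ``flagged``.  A trial whose large outward
    or return saccade was not detected yields flagged records.
    """
    periods = segment_fixations(
        trace, saccades, trajectory.fixation_schedule(), min_amplitude
    )
    complete = len(periods) >= 3 and not any(p.flagged for p in periods)
    return [
        {
            "position": p.position,
            "error_deg": absolute_fixation_error(p),
            "n_valid": p.n_valid,
            "flagged": p.flagged or not complete,
        }
        for p in periods
    ]


def aggregate_fixation_errors(records: pd.DataFrame) -> pd.DataFrame:
    """Across-subject summary of absolute fixation errors.

    ``records`` must have columns ``subject``, ``system``, ``position`` and
    ``error_deg`` with one row per trial.  Per subject and position the trial
    errors are averaged first; the table then reports, per system and
    position, the across-subject mean, SD (n-1 denominator) and subject
    count, plus an ``ALL`` row per system averaging each subject's
    per-position means across positions before taking the across-subject
    mean and SD.
    """
    if records.empty:
        return pd.DataFrame(
            columns=["system", "position", "mean_deg", "sd_deg", "n_subjects"]
        )
    per_subj = (
        records.groupby(["system", "position", "subject"], sort=True)["error_deg"]
        .mean()
        .rename("mean_deg")
    )
    by_pos = (
        per_subj.groupby(["system", "position"])
        .agg(mean_deg="mean", sd_deg="std", n_subjects="count")
        .reset_index()
    )
    overall = (
        per_subj.groupby(["system", "subject"]).mean()
        .groupby("system")
        .agg(mean_deg="mean", sd_deg="std", n_subjects="count")
        .reset_index()
    )
    overall.insert(1, "position", "ALL")
    return pd.concat([by_pos, overall], ignore_index=True)


__all__ = [
    "FixationPeriod",
    "segment_fixations",
    "absolute_fixation_error",
    "fixation_errors_for_trial",
    "aggregate_fixation_errors",
    "DELIMITER_AMPLITUDE",
]
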