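"""Smooth-pursuit velocity-gain estimation.

Velocity gain is the ratio of eye velocity to target velocity; 1.0 is
perfect tracking and values below 1.0 mean the eye lags the target.  Gain is
computed only during steady-state pursuit, which begins 300 ms after the
initial saccade toward the pursuit target has landed, and data segments
containing catch-up saccades are excluded from 40 ms before saccade onset
until 60 ms after saccade offset.

The overall gain uses the mean instantaneous Euclidean speed of the eye over
the kept samples, divided by the target speed.  For circular pursuit this
Euclidean combination of the horizontal and vertical velocity components is
deliberately retained even though zero-mean velocity noise inflates it
(Jensen's inequality: ``E|g*vt + eps| >= g*|vt|`` with equality iff the noise
vanishes) -- that inflation is precisely how a circular-pursuit gain can
exceed 1.0 while each directional component, analyzed separately, stays below
1.0.  The per-axis component gain is the through-origin least-squares slope
of the eye component velocity on the target component velocity, which is
unbiased under zero-mean noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .detect import SaccadeEvent
from .trace import TIME_EPS, VelocityTrace

log = logging.getLogger(__name__)

#: steady-state pursuit begins this long after the initial saccade lands (s)
SETTLE_S = 0.300
#: padding removed around catch-up saccades (s)
CATCHUP_PRE_S = 0.040
CATCHUP_POST_S = 0.060
#: trials with less kept steady-state data than this are dropped (s)
MIN_KEPT_S = 0.200


@dataclass
class SteadyStateWindow:
    """Steady-state analysis window of one pursuit trial."""

    t0: float
    t1: float
    flagged: bool
    initial_saccade: SaccadeEvent | None = None

    @property
    def empty(self) -> bool:
        return self.t1 <= self.t0


def steady_state_window(
    pursuit_start: float,
    pursuit_end: float,
    saccades: Sequence[SaccadeEvent],
    settle_s: float = SETTLE_S,
    edge_margin_s: float = 0.0,
) -> SteadyStateWindow:
    """Locate the steady-state window of a pursuit segment.

    The initial saccade is the first detected saccade at or after the pursuit
    target onset; the window runs from its offset plus ``settle_s`` to the
    end of the pursuit segment (optionally shortened by ``edge_margin_s``,
    e.g. to keep a velocity smoother's support inside the segment).  If no
    initial saccade is found the window is anchored at the pursuit onset
    instead and flagged; a window that comes out empty is flagged too.
    """
    cands = [
        s for s in saccades
        if s.onset_t >= pursuit_start - TIME_EPS and s.onset_t < pursuit_end
    ]
    if cands:
        s0 = min(cands, key=lambda s: s.onset_t)
        t0 = s0.offset_t + settle_s
        flagged = False
    else:
        s0 = None
        t0 = pursuit_start + settle_s
        flagged = True
    t1 = pursuit_end - edge_margin_s
    if t1 <= t0:
        flagged = True
    return SteadyStateWindow(t0=float(t0), t1=float(t1), flagged=flagged,
                             initial_saccade=s0)


def exclude_catchup(
    window: SteadyStateWindow | tuple[float, float],
    saccades: Sequence[SaccadeEvent],
    pre_s: float = CATCHUP_PRE_S,
    post_s: float = CATCHUP_POST_S,
) -> list[tuple[float, float]]:
    """Remove padded catch-up-saccade intervals from a window.

    Subtracts ``[onset - pre_s, offset + post_s]`` around every saccade
    overlapping the window and returns the remaining sub-intervals (possibly
    an empty list).
    """
    if isinstance(window, SteadyStateWindow):
        t0, t1 = window.t0, window.t1
    else:
        t0, t1 = window
    kept = [(t0, t1)] if t1 > t0 else []
    for s in sorted(saccades, key=lambda s: s.onset_t):
        a, b = s.onset_t - pre_s, s.offset_t + post_s
        nxt: list[tuple[float, float]] = []
        for k0, k1 in kept:
            if b <= k0 or a >= k1:
                nxt.append((k0, k1))
                continue
            if a > k0:
                nxt.append((k0, a))
            if b < k1:
                nxt.append((b, k1))
        kept = nxt
    return kept


def _kept_mask(vel: VelocityTrace, intervals: Sequence[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(vel.n, bool)
    for a, b in intervals:
        mask |= (vel.time >= a - TIME_EPS) & (vel.time <= b + TIME_EPS)
    return mask & vel.valid


def kept_duration(intervals: Sequence[tuple[float, float]]) -> float:
    return float(sum(max(b - a, 0.0) for a, b in intervals))


def velocity_gain_linear(
    vel: VelocityTrace,
    intervals: Sequence[tuple[float, float]],
    target_speed: float,
) -> float | None:
    """Mean Euclidean eye speed over the kept samples / target speed.

    Returns ``None`` (undefined) when no valid samples remain.
    """
    if target_speed <= 0:
        raise ValueError("target_speed must be positive")
    mask = _kept_mask(vel, intervals)
    if not mask.any():
        log.warning("no kept samples in pursuit window; gain undefined")
        return None
    return float(np.mean(vel.speed[mask]) / target_speed)


def velocity_gain_circular(
    vel: VelocityTrace,
    intervals: Sequence[tuple[float, float]],
    target_vx: np.ndarray,
    target_vy: np.ndarray,
    target_speed: float,
) -> tuple[float, tuple[float, float]] | None:
    """Overall Euclidean gain and per-axis component gains for circular pursuit.

    ``target_vx``/``target_vy`` are the target's component velocities on the
    same grid as ``vel``.  The component gain per axis is the through-origin
    least-squares slope of eye on target component velocity over the kept
    samples.  Returns ``None`` when no valid samples remain.
    """
    if target_speed <= 0:
        raise ValueError("target_speed must be positive")
    mask = _kept_mask(vel, intervals)
    if not mask.any():
        log.warning("no kept samples in pursuit window; gain undefined")
        return None
    overall = float(np.mean(vel.speed[mask]) / target_speed)
    comps = []
    for ve, vt in ((vel.vx, target_vx), (vel.vy, target_vy)):
        vt_m = np.asarray(vt, float)[mask]
        denom = float(np.dot(vt_m, vt_m))
        if denom <= 0:
            comps.append(np.nan)
        else:
            comps.append(float(np.dot(ve[mask], vt_m) / denom))
    return overall, (comps[0], comps[1])


@dataclass
class PursuitTrialMetrics:
    """Per-trial pursuit summary (see module docstring for definitions)."""

    paradigm: str            # "linear" | "circular"
    condition: str           # direction or start-phase label
    gain: float | None
    component_gains: tuple[float, float] | None
    n_excluded_segments: int
    kept_s: float
    flagged: bool


__all__ = [
    "SteadyStateWindow",
    "steady_state_window",
    "exclude_catchup",
    "velocity_gain_linear",
    "velocity_gain_circular",
    "kept_duration",
    "PursuitTrialMetrics",
    "SETTLE_S",
    "CATCHUP_PRE_S",
    "CATCHUP_POST_S",
    "MIN_KEPT_S",
]
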