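"""Synthetic target trajectories and eye traces with known ground truth.

Three paradigms are generated, mirroring a standard oculomotor test battery:

* a visually guided **saccade task** -- 1 s central fixation, jump to one of
  eight targets 45 deg apart at 10 deg eccentricity, 2 s hold, jump back,
  1 s hold;
* a **step-ramp** (Rashbass) pursuit task -- step to 10 deg in one of the four
  cardinal directions, then centripetal motion at 10 deg/s for 2 s, crossing
  the center and ending at the opposite position;
* a **circular pursuit** task -- step to a random phase on a 5-deg-radius
  circle, clockwise motion at a tangential speed of 10 deg/s for 5/4 orbits
  (about 3.9 s), then back to center.

The simulated eye obeys the standard behavioral regularities: saccades follow
a minimum-jerk waveform with a main-sequence duration model (default
``D(ms) = 2.2*A(deg) + 21``, giving ~43 ms and a ~436 deg/s peak for 10 deg),
primary saccades undershoot the target step by ~10%, pursuit tracks the
target velocity at a configurable gain with corrective/catch-up saccades
closing accumulated position error, and white fixation noise, slow drift,
blinks (validity loss) and a polynomial calibration-offset field are layered
on top.  Everything injected is recorded in a :class:`GroundTruth` object so
downstream detection and metric recovery can be validated exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .trace import EyeTrace

#: peak velocity of a minimum-jerk displacement, in units of amplitude/duration
MIN_JERK_PEAK_FACTOR = 1.875


# ---------------------------------------------------------------------------
# target trajectories
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """Labeled interval of a target trajectory.

    ``label`` is one of ``fixation``, ``jump``, ``ramp``, ``orbit``; ``jump``
    segments are zero-length markers at the step instant.  ``params`` carries
    per-segment geometry (target position, direction, speed, radius, phase).
    """

    label: str
    t0: float
    t1: float
    params: dict = field(default_factory=dict)


@dataclass
class TargetTrajectory:
    """Piecewise target path on a uniform time grid, with paradigm metadata."""

    time: np.ndarray
    tx: np.ndarray
    ty: np.ndarray
    segments: list[Segment]
    rate: float
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.time.size

    def fixation_schedule(self) -> list[Segment]:
        """The fixation segments, i.e. the target schedule for fixation analysis."""
        return [s for s in self.segments if s.label == "fixation"]

    def pursuit_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.label in ("ramp", "orbit")]


def _grid(total_s: float, rate: float) -> np.ndarray:
    n = int(round(total_s * rate)) + 1
    return np.arange(n) / rate


#: polar angles (deg) of the eight saccade-task targets, 45 deg apart
EIGHT_DIRECTIONS = np.arange(8) * 45.0

#: the four cardinal step-ramp directions as unit vectors
CARDINALS = {
    "right": (1.0, 0.0),
    "up": (0.0, 1.0),
    "left": (-1.0, 0.0),
    "down": (0.0, -1.0),
}


def _balanced_draw(rng: np.random.Generator, n_options: int, n_trials: int) -> np.ndarray:
    """Seeded random order covering all options before repeating any."""
    blocks = []
    while sum(len(b) for b in blocks) < n_trials:
        blocks.append(rng.permutation(n_options))
    return np.concatenate(blocks)[:n_trials]


def saccade_trial(direction: int, rate: float, trial: int = 0) -> TargetTrajectory:
    """One saccade-task trajectory toward target index ``direction`` (0..7)."""
    ang = math.radians(EIGHT_DIRECTIONS[direction])
    px, py = 10.0 * math.cos(ang), 10.0 * math.sin(ang)
    t = _grid(4.0, rate)
    tx = np.zeros_like(t)
    ty = np.zeros_like(t)
    hold = (t >= 1.0) & (t < 3.0)
    tx[hold], ty[hold] = px, py
    segs = [
        Segment("fixation", 0.0, 1.0, {"target": (0.0, 0.0), "position": "C"}),
        Segment("jump", 1.0, 1.0, {"to": (px, py)}),
        Segment("fixation", 1.0, 3.0,
                {"target": (px, py), "position": f"P{direction}"}),
        Segment("jump", 3.0, 3.0, {"to": (0.0, 0.0)}),
        Segment("fixation", 3.0, 4.0, {"target": (0.0, 0.0), "position": "C2"}),
    ]
    return TargetTrajectory(
        t, tx, ty, segs, rate,
        {"paradigm": "saccade", "trial": trial, "direction": int(direction)},
    )


def make_saccade_task(
    n_trials: int, rate: float, seed: int | None = 0
) -> list[TargetTrajectory]:
    """Saccade-task target trajectories (4 s each).

    1 s center fixation, jump to one of eight targets at 10 deg eccentricity
    (45 deg apart, order seeded-random and balanced), 2 s hold, jump back,
    1 s hold.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    dirs = _balanced_draw(rng, 8, n_trials)
    return [saccade_trial(int(d), rate, k) for k, d in enumerate(dirs)]


def make_step_ramp(
    n_trials: int, rate: float, seed: int | None = 0, speed: float = 10.0
) -> list[TargetTrajectory]:
    """Step-ramp pursuit trajectories (4 s each).

    1 s fixation, step to 10 deg in one of the four cardinal directions, then
    centripetal constant-speed motion (10 deg/s) for 2 s, ending at the
    opposite position, then 1 s central fixation.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(CARDINALS)
    dirs = _balanced_draw(rng, 4, n_trials)
    return [step_ramp_trial(names[d], rate, k, speed) for k, d in enumerate(dirs)]


def step_ramp_trial(
    direction: str, rate: float, trial: int = 0, speed: float = 10.0
) -> TargetTrajectory:
    """One step-ramp trajectory stepping toward the named cardinal direction."""
    ux, uy = CARDINALS[direction]
    t = _grid(4.0, rate)
    tx = np.zeros_like(t)
    ty = np.zeros_like(t)
    ramp = (t >= 1.0) & (t < 3.0)
    # position = 10*u - speed*u*(t-1): through center at t=2, -10*u at t=3
    tx[ramp] = ux * (10.0 - speed * (t[ramp] - 1.0))
    ty[ramp] = uy * (10.0 - speed * (t[ramp] - 1.0))
    segs = [
        Segment("fixation", 0.0, 1.0, {"target": (0.0, 0.0), "position": "C"}),
        Segment("jump", 1.0, 1.0, {"to": (10.0 * ux, 10.0 * uy)}),
        Segment("ramp", 1.0, 3.0,
                {"direction": direction, "speed": speed,
                 "start": (10.0 * ux, 10.0 * uy)}),
        Segment("jump", 3.0, 3.0, {"to": (0.0, 0.0)}),
        Segment("fixation", 3.0, 4.0, {"target": (0.0, 0.0), "position": "C2"}),
    ]
    return TargetTrajectory(
        t, tx, ty, segs, rate,
        {"paradigm": "step_ramp", "trial": trial, "direction": direction},
    )


def make_circular(
    n_trials: int, rate: float, seed: int | None = 0,
    radius: float = 5.0, speed: float = 10.0, orbits: float = 1.25,
) -> list[TargetTrajectory]:
    """Circular pursuit trajectories.

    1 s fixation, step to a seeded-random phase on a circle of the given
    radius, clockwise motion at the given tangential speed for ``orbits``
    revolutions (5/4 orbits at r=5 deg and 10 deg/s lasts 5*pi/4 ~ 3.93 s),
    jump back to center, 1 s fixation.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    return [
        circular_trial(rng.uniform(0.0, 2.0 * math.pi), rate, k,
                       radius, speed, orbits)
        for k in range(n_trials)
    ]


def circular_trial(
    phase0: float, rate: float, trial: int = 0,
    radius: float = 5.0, speed: float = 10.0, orbits: float = 1.25,
) -> TargetTrajectory:
    """One circular-pursuit trajectory starting at the given phase (rad)."""
    omega = speed / radius  # rad/s
    t_orbit = orbits * 2.0 * math.pi / omega
    total = 1.0 + t_orbit + 1.0
    t = _grid(total, rate)
    tx = np.zeros_like(t)
    ty = np.zeros_like(t)
    orbit = (t >= 1.0) & (t < 1.0 + t_orbit)
    theta = phase0 - omega * (t[orbit] - 1.0)  # clockwise
    tx[orbit] = radius * np.cos(theta)
    ty[orbit] = radius * np.sin(theta)
    p0 = (radius * math.cos(phase0), radius * math.sin(phase0))
    segs = [
        Segment("fixation", 0.0, 1.0, {"target": (0.0, 0.0), "position": "C"}),
        Segment("jump", 1.0, 1.0, {"to": p0}),
        Segment("orbit", 1.0, 1.0 + t_orbit,
                {"radius": radius, "speed": speed, "phase0": phase0}),
        Segment("jump", 1.0 + t_orbit, 1.0 + t_orbit, {"to": (0.0, 0.0)}),
        Segment("fixation", 1.0 + t_orbit, total,
                {"target": (0.0, 0.0), "position": "C2"}),
    ]
    return TargetTrajectory(
        t, tx, ty, segs, rate,
        {"paradigm": "circular", "trial": trial, "phase0_rad": float(phase0)},
    )


def trajectory_from_meta(meta: dict, rate: float | None = None) -> TargetTrajectory:
    """Rebuild a target trajectory from trace sidecar metadata.

    Uses ``paradigm`` plus the per-trial parameter (``direction`` for the
    saccade and step-ramp tasks, ``phase0_rad`` for circular pursuit) and the
    sampling rate (``rate_hz`` key or the ``rate`` argument).
    """
    r = float(rate if rate is not None else meta["rate_hz"])
    paradigm = meta["paradigm"]
    trial = int(meta.get("trial", 0))
    if paradigm == "saccade":
        return saccade_trial(int(meta["direction"]), r, trial)
    if paradigm == "step_ramp":
        return step_ramp_trial(str(meta["direction"]), r, trial)
    if paradigm == "circular":
        return circular_trial(float(meta["phase0_rad"]), r, trial)
    raise ValueError(f"unknown paradigm {paradigm!r}")


# ---------------------------------------------------------------------------
# saccade waveform
# ---------------------------------------------------------------------------

def minimum_jerk_profile(tau):
    """Normalized minimum-jerk displacement ``10*tau^3 - 15*tau^4 + 6*tau^5``.

    Monotone from 0 at ``tau=0`` to 1 at ``tau=1`` with zero velocity and
    acceleration at both endpoints; peak normalized velocity 1.875 at
    ``tau=0.5``.
    """
    tau = np.clip(tau, 0.0, 1.0)
    return tau ** 3 * (10.0 - 15.0 * tau + 6.0 * tau ** 2)


def minimum_jerk_saccade(amplitude: float, duration: float) -> Callable[[np.ndarray], np.ndarray]:
    """Displacement-vs-time function of a minimum-jerk saccade.

    Returns ``s(t)`` with ``s(0)=0`` and ``s(duration)=amplitude``; the peak
    velocity of the profile is ``1.875*amplitude/duration``.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if amplitude == 0:
        raise ValueError("amplitude must be nonzero")

    def s(t):
        return amplitude * minimum_jerk_profile(np.asarray(t, float) / duration)

    s.amplitude = amplitude
    s.duration = duration
    s.peak_velocity = MIN_JERK_PEAK_FACTOR * abs(amplitude) / duration
    return s


# ---------------------------------------------------------------------------
# calibration-offset field
# ---------------------------------------------------------------------------

#: ordering of the polynomial basis terms used by CalibrationField
FIELD_BASIS = ("1", "x", "y", "x2", "xy", "y2")


@dataclass
class CalibrationField:
    """Quadratic polynomial field mapping true gaze to an additive offset.

    ``dx(x, y)`` and ``dy(x, y)`` are each a linear combination of the basis
    ``(1, x, y, x^2, x*y, y^2)`` with the coefficient vectors ``cx`` and
    ``cy``.  The offset at the origin equals the constant terms
    ``(cx[0], cy[0])``.  Such a field is a configurable stand-in for the
    spatially systematic accuracy errors of a video-based tracker (e.g. larger
    errors in one vertical hemifield than the other); it makes no claim about
    their physical cause.
    """

    cx: np.ndarray = field(default_factory=lambda: np.zeros(6))
    cy: np.ndarray = field(default_factory=lambda: np.zeros(6))

    def __post_init__(self) -> None:
        self.cx = np.asarray(self.cx, float)
        self.cy = np.asarray(self.cy, float)
        if self.cx.shape != (6,) or self.cy.shape != (6,):
            raise ValueError("cx and cy must each have 6 coefficients "
                             f"(basis {FIELD_BASIS})")

    @classmethod
    def zero(cls) -> "CalibrationField":
        return cls()

    @classmethod
    def constant(cls, dx: float, dy: float) -> "CalibrationField":
        f = cls()
        f.cx[0], f.cy[0] = dx, dy
        return f

    def offset(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate the (dx, dy) offset at true position(s) ``(x, y)``."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        basis = np.stack(
            [np.ones_like(x), x, y, x * x, x * y, y * y], axis=-1
        )
        return basis @ self.cx, basis @ self.cy


def apply_calibration_field(trace: EyeTrace, field_: CalibrationField) -> EyeTrace:
    """Add the field's offset, evaluated at each sample's position, to a trace."""
    out = trace.copy()
    dx, dy = field_.offset(trace.x, trace.y)
    out.x = out.x + dx
    out.y = out.y + dy
    return out


# ---------------------------------------------------------------------------
# simulation configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Tunable behavioral and noise parameters of the eye simulator.

    Defaults emulate a healthy adult tracked by a video-based system:
    saccadic latency 200 +/- 30 ms (truncated at 80 ms), ~10% primary-saccade
    undershoot, main-sequence duration ``2.2*A + 21`` ms, pursuit velocity
    gain slightly below 1, white position noise of 0.05 deg SD, slow fixation
    drift of 0.05 deg/s SD, and blinks at 0.1 events/s lasting 100-300 ms.
    """

    rate: float = 500.0
    latency_mean: float = 0.200
    latency_sd: float = 0.030
    latency_min: float = 0.080
    undershoot_frac: float = 0.10
    main_sequence_slope: float = 2.2    # ms per degree
    main_sequence_intercept: float = 21.0  # ms
    pursuit_gain: float = 0.9
    fixation_noise_sd: float = 0.05     # deg
    drift_rate_sd: float = 0.05         # deg/s
    blink_rate: float = 0.1             # events/s
    blink_duration_range: tuple[float, float] = (0.100, 0.300)
    catchup_threshold: float = 1.0      # deg, during pursuit
    correction_threshold: float = 0.75  # deg, during fixation
    refractory: float = 0.100           # s, after a saccade ends
    distortion: CalibrationField = field(default_factory=CalibrationField.zero)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.undershoot_frac < 1.0):
            raise ValueError("undershoot_frac must be in [0, 1)")
        if self.pursuit_gain <= 0:
            raise ValueError("pursuit_gain must be positive")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def saccade_duration(self, amplitude: float) -> float:
        """Main-sequence saccade duration in seconds for a given amplitude."""
        return (self.main_sequence_slope * amplitude
                + self.main_sequence_intercept) / 1000.0


@dataclass
class TrueSaccade:
    onset_t: float
    offset_t: float
    amplitude: float
    peak_velocity: float
    kind: str  # "primary" | "corrective" | "catchup"


@dataclass
class GroundTruth:
    """Everything the simulator injected, for use as an analysis oracle."""

    saccades: list[TrueSaccade] = field(default_factory=list)
    blinks: list[tuple[float, float]] = field(default_factory=list)
    pursuit_gain: float = 1.0
    target_offsets: dict = field(default_factory=dict)  # position label -> (dx, dy)


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

#: per-sample target displacement above which a step counts as a jump (deg)
_JUMP_STEP = 1.0


def _draw_latency(rng: np.random.Generator, cfg: SimulationConfig) -> float:
    return max(cfg.latency_min, rng.normal(cfg.latency_mean, cfg.latency_sd))


def simulate_trace(
    trajectory: TargetTrajectory,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[EyeTrace, GroundTruth]:
    """Simulate an eye trace following a target trajectory.

    The ideal (noise-free) eye path is built first: target jumps trigger
    primary saccades after a seeded latency, with amplitude
    ``(1 - undershoot_frac)`` times the instantaneous position error and a
    minimum-jerk waveform whose duration follows the main-sequence model;
    during ramp/orbit segments the eye moves at ``pursuit_gain`` times the
    target velocity; position errors beyond the catch-up (pursuit) or
    correction (fixation) threshold trigger secondary saccades that close the
    full remaining error.  White noise, per-segment drift, blinks (validity
    loss) and the calibration-offset field are then layered on top.

    Returns the trace and a :class:`GroundTruth` record of everything
    injected.  Passing the same config/seed yields bit-identical output.
    """
    if abs(trajectory.rate - config.rate) > 1e-9:
        raise ValueError(
            f"trajectory rate {trajectory.rate} Hz and config rate "
            f"{config.rate} Hz are incompatible"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)

    t = trajectory.time
    n = t.size
    dt = 1.0 / trajectory.rate
    tx, ty = trajectory.tx, trajectory.ty

    # per-sample segment context
    pursuit_mask = np.zeros(n, bool)
    for seg in trajectory.pursuit_segments():
        pursuit_mask |= (t >= seg.t0 - 1e-9) & (t < seg.t1 - 1e-9)
    fix_segs = trajectory.fixation_schedule()
    fix_id = np.full(n, -1)
    for j, seg in enumerate(fix_segs):
        m = (t >= seg.t0 - 1e-9) & (t < seg.t1 - 1e-9)
        fix_id[m] = j
    fix_id[-1] = len(fix_segs) - 1 if fix_segs else -1

    # target jumps -> pre-scheduled primary saccades
    step = np.hypot(np.diff(tx), np.diff(ty))
    jump_idx = (np.nonzero(step > _JUMP_STEP)[0] + 1).tolist()
    primaries = []  # (jump index, onset index)
    for j in jump_idx:
        onset = t[j] + _draw_latency(rng, config)
        primaries.append((int(j), int(round((onset - t[0]) / dt))))
    p_next = 0

    gt = GroundTruth(pursuit_gain=config.pursuit_gain)
    for seg in fix_segs:
        dx0, dy0 = config.distortion.offset(*seg.params["target"])
        gt.target_offsets[seg.params["position"]] = (float(dx0), float(dy0))

    ex = np.empty(n)
    ey = np.empty(n)
    ex[0], ey[0] = tx[0], ty[0]

    sac = None          # active saccade: (t0, t1, D, x0, y0, vec_x, vec_y)
    reactive_i = None   # scheduled corrective/catch-up onset index
    reactive_kind = ""
    last_end = -np.inf
    drift_v = (0.0, 0.0)
    cur_fix = fix_id[0]
    if cur_fix >= 0 and config.drift_rate_sd > 0:
        drift_v = tuple(rng.normal(0.0, config.drift_rate_sd, 2))

    def launch(i: int, kind: str):
        nonlocal sac, last_end
        x0, y0 = ex[i], ey[i]
        dx_, dy_ = tx[i] - x0, ty[i] - y0
        full = math.hypot(dx_, dy_)
        if full < 0.05:
            return
        amp = full * (1.0 - config.undershoot_frac) if kind == "primary" else full
        dur = max(config.saccade_duration(amp), 2.0 * dt)
        ux_, uy_ = dx_ / full, dy_ / full
        sac = (t[i], t[i] + dur, dur, x0, y0, amp * ux_, amp * uy_)
        gt.saccades.append(TrueSaccade(
            onset_t=float(t[i]), offset_t=float(min(t[i] + dur, t[-1])),
            amplitude=float(amp),
            peak_velocity=float(MIN_JERK_PEAK_FACTOR * amp / dur),
            kind=kind,
        ))

    for i in range(1, n):
        # new fixation segment -> new drift velocity
        if fix_id[i] != cur_fix:
            cur_fix = fix_id[i]
            if cur_fix >= 0 and config.drift_rate_sd > 0:
                drift_v = tuple(rng.normal(0.0, config.drift_rate_sd, 2))
        # position update
        if sac is not None:
            t0s, t1s, dur, x0, y0, vx_, vy_ = sac
            if t[i] >= t1s - 1e-12:  # saccade complete: snap to landing point
                ex[i] = x0 + vx_
                ey[i] = y0 + vy_
                last_end = t1s
                sac = None
            else:
                p = minimum_jerk_profile((t[i] - t0s) / dur)
                ex[i] = x0 + vx_ * p
                ey[i] = y0 + vy_ * p
        else:
            if pursuit_mask[i]:
                ddx, ddy = tx[i] - tx[i - 1], ty[i] - ty[i - 1]
                if math.hypot(ddx, ddy) <= _JUMP_STEP:
                    ex[i] = ex[i - 1] + config.pursuit_gain * ddx
                    ey[i] = ey[i - 1] + config.pursuit_gain * ddy
                else:  # the target jumped; the eye holds until its saccade
                    ex[i], ey[i] = ex[i - 1], ey[i - 1]
            else:
                ex[i] = ex[i - 1] + drift_v[0] * dt
                ey[i] = ey[i - 1] + drift_v[1] * dt

        if sac is not None:
            continue

        # launch due saccades (primary takes precedence; it supersedes any
        # scheduled secondary, whose error it will close anyway)
        if p_next < len(primaries) and i >= primaries[p_next][1]:
            p_next += 1
            reactive_i = None
            launch(i, "primary")
            continue
        if reactive_i is not None and i >= reactive_i:
            kind = reactive_kind
            reactive_i = None
            launch(i, kind)
            continue

        # schedule a secondary saccade when the position error accumulates,
        # but never in response to a target step a pending primary will handle
        primary_pending = (p_next < len(primaries)
                           and i >= primaries[p_next][0])
        if (reactive_i is None and not primary_pending
                and t[i] - last_end > config.refractory):
            err = math.hypot(tx[i] - ex[i], ty[i] - ey[i])
            thr = (config.catchup_threshold if pursuit_mask[i]
                   else config.correction_threshold)
            if err > thr:
                onset = t[i] + _draw_latency(rng, config)
                oi = int(round((onset - t[0]) / dt))
                next_jump = primaries[p_next][0] if p_next < len(primaries) else n
                if oi < min(n, next_jump):
                    reactive_i = oi
                    reactive_kind = "catchup" if pursuit_mask[i] else "corrective"

    # measurement noise
    x_out = ex + rng.normal(0.0, config.fixation_noise_sd, n) \
        if config.fixation_noise_sd > 0 else ex.copy()
    y_out = ey + rng.normal(0.0, config.fixation_noise_sd, n) \
        if config.fixation_noise_sd > 0 else ey.copy()

    # calibration offset, evaluated at the true eye position
    off_x, off_y = config.distortion.offset(ex, ey)
    x_out = x_out + off_x
    y_out = y_out + off_y

    # blinks as validity loss
    valid = np.ones(n, bool)
    duration = t[-1] - t[0]
    if config.blink_rate > 0:
        n_blinks = rng.poisson(config.blink_rate * duration)
        for _ in range(n_blinks):
            d = rng.uniform(*config.blink_duration_range)
            onset = rng.uniform(0.0, max(duration - d, 0.0))
            valid[(t >= t[0] + onset) & (t <= t[0] + onset + d)] = False
            gt.blinks.append((float(t[0] + onset), float(t[0] + onset + d)))

    meta = dict(trajectory.meta)
    meta.setdefault("rate_hz", trajectory.rate)
    eye = EyeTrace(t.copy(), x_out, y_out, valid, trajectory.rate, meta)
    return eye, gt


def make_two_saccade_trace(
    rate: float = 500.0,
    primary_amp: float = 10.0,
    corrective_amp: float = 1.0,
    config: SimulationConfig | None = None,
) -> tuple[EyeTrace, GroundTruth]:
    """Noise-free horizontal trace with one large and one small saccade.

    A clean minimal scenario for contrasting the two saccade detectors: a
    primary saccade of ``primary_amp`` (main-sequence duration, peak well
    above 100 deg/s) followed 300 ms later by a corrective saccade of
    ``corrective_amp`` whose peak velocity stays below 100 deg/s but above
    30 deg/s.
    """
    cfg = config or SimulationConfig(rate=rate)
    dt = 1.0 / rate
    t = _grid(2.0, rate)
    x = np.zeros_like(t)
    gt = GroundTruth()
    for onset, amp in ((0.5, primary_amp), (0.5 + cfg.saccade_duration(primary_amp) + 0.3,
                                            corrective_amp)):
        dur = max(cfg.saccade_duration(amp), 2.0 * dt)
        s = minimum_jerk_saccade(amp, dur)
        m = t >= onset - 1e-12
        x[m] += s(np.minimum(t[m] - onset, dur))
        gt.saccades.append(TrueSaccade(
            onset_t=onset, offset_t=onset + dur, amplitude=amp,
            peak_velocity=s.peak_velocity,
            kind="primary" if amp == primary_amp else "corrective",
        ))
    trace = EyeTrace(t, x, np.zeros_like(t), np.ones_like(t, bool), rate,
                     {"paradigm": "two_saccade_demo"})
    return trace, gt


__all__ = [
    "Segment",
    "TargetTrajectory",
    "SimulationConfig",
    "CalibrationField",
    "GroundTruth",
    "TrueSaccade",
    "make_saccade_task",
    "make_step_ramp",
    "make_circular",
    "saccade_trial",
    "step_ramp_trial",
    "circular_trial",
    "trajectory_from_meta",
    "minimum_jerk_profile",
    "minimum_jerk_saccade",
    "apply_calibration_field",
    "simulate_trace",
    "make_two_saccade_trace",
    "MIN_JERK_PEAK_FACTOR",
    "EIGHT_DIRECTIONS",
    "CARDINALS",
]
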