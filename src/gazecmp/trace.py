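"""Core gaze-signal containers and shared signal operations.

All positions are in degrees of visual angle, time in seconds, velocities in
deg/s.  A trace is a uniformly sampled monocular gaze stream with a per-sample
validity mask (``False`` during signal loss, e.g. blinks).  Event and
exclusion windows are closed intervals in time; sample membership is decided
by timestamp with a one-nanosecond tolerance so that exact grid points on the
interval boundary are always included.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

#: tolerance for timestamp comparisons (seconds)
TIME_EPS = 1e-9


def _as_float_array(a) -> np.ndarray:
    return np.asarray(a, dtype=float)


@dataclass
class EyeTrace:
    """Uniformly sampled monocular gaze position series.

    Parameters
    ----------
    time : array of float
        Sample times in seconds, strictly increasing with uniform step
        ``1/rate`` (checked to within 1 ns).
    x, y : array of float
        Horizontal / vertical gaze position in degrees of visual angle.
    valid : array of bool
        ``False`` where the signal is lost (blinks, tracking dropouts) or has
        been masked out by an exclusion window.
    rate : float
        Sampling frequency in Hz.
    meta : dict
        Free-form metadata (``subject``, ``trial``, ``system``, ``paradigm``).
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = _as_float_array(self.time)
        self.x = _as_float_array(self.x)
        self.y = _as_float_array(self.y)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        n = self.time.size
        if not (self.x.size == self.y.size == self.valid.size == n):
            raise ValueError(
                "time, x, y and valid must have equal length "
                f"(got {n}, {self.x.size}, {self.y.size}, {self.valid.size})"
            )
        if n >= 2:
            steps = np.diff(self.time)
            dev = np.max(np.abs(steps - 1.0 / self.rate))
            if dev >= TIME_EPS:
                raise ValueError(
                    f"time grid not uniform at 1/rate: max step deviation {dev:g} s"
                )

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        """Span from first to last sample in seconds."""
        return float(self.time[-1] - self.time[0]) if self.n else 0.0

    def copy(self) -> "EyeTrace":
        return EyeTrace(
            self.time.copy(), self.x.copy(), self.y.copy(),
            self.valid.copy(), self.rate, dict(self.meta),
        )


@dataclass
class VelocityTrace:
    """Eye velocity and acceleration derived from an :class:`EyeTrace`.

    ``speed`` is the Euclidean combination of the component velocities and
    ``accel`` the derivative of speed (deg/s^2).  ``valid`` marks samples
    whose finite-difference stencil touched only valid position samples.
    """

    time: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    speed: np.ndarray
    accel: np.ndarray
    valid: np.ndarray
    rate: float

    @property
    def n(self) -> int:
        return self.time.size


def euclidean_speed(vx, vy):
    """Euclidean combination of horizontal and vertical velocity components.

    Returns ``sqrt(vx**2 + vy**2)`` elementwise; works on scalars and arrays.
    """
    return np.hypot(vx, vy)


def compute_velocity(
    trace: EyeTrace,
    smooth_window: int | None = None,
    smooth_polyorder: int = 2,
) -> VelocityTrace:
    """Differentiate a gaze trace into velocity, speed and acceleration.

    Component velocities come from central differences on interior samples and
    one-sided differences at the endpoints; acceleration is the same operator
    applied to the speed signal.  No pre-smoothing is applied by default: the
    detector thresholds are defined on the raw velocity signal.  An optional
    Savitzky-Golay smoother (applied to the position signals before
    differentiation) is available via ``smooth_window`` (odd sample count) and
    ``smooth_polyorder``.

    A velocity sample is valid only if the three position samples under its
    stencil (one-sided at the ends) are all valid; the acceleration shares
    this mask.
    """
    if trace.n < 3:
        raise ValueError(
            f"need at least 3 samples to differentiate, got {trace.n}"
        )
    x, y = trace.x, trace.y
    if smooth_window is not None:
        if smooth_window % 2 == 0 or smooth_window < smooth_polyorder + 1:
            raise ValueError(
                f"smooth_window must be odd and > polyorder, got {smooth_window}"
            )
        x = savgol_filter(x, smooth_window, smooth_polyorder)
        y = savgol_filter(y, smooth_window, smooth_polyorder)
    dt = trace.dt
    vx = np.gradient(x, dt)
    vy = np.gradient(y, dt)
    speed = euclidean_speed(vx, vy)
    accel = np.gradient(speed, dt)
    v = trace.valid
    left = np.concatenate(([v[0]], v[:-1]))
    right = np.concatenate((v[1:], [v[-1]]))
    vvalid = v & left & right
    return VelocityTrace(
        time=trace.time.copy(), vx=vx, vy=vy, speed=speed,
        accel=accel, valid=vvalid, rate=trace.rate,
    )


def resample(trace: EyeTrace, new_rate: float) -> EyeTrace:
    """Linearly interpolate a trace onto a new uniform grid.

    The new grid spans the same time range (the last partial sample period is
    dropped).  A resampled sample is valid only if both bracketing source
    samples are valid; samples landing exactly on a source sample inherit its
    validity.
    """
    if new_rate <= 0:
        raise ValueError(f"new_rate must be positive, got {new_rate}")
    if trace.n == 0:
        raise ValueError("cannot resample an empty trace")
    t0 = trace.time[0]
    n_new = int(np.floor(trace.duration * new_rate + TIME_EPS)) + 1
    t_new = t0 + np.arange(n_new) / new_rate
    x = np.interp(t_new, trace.time, trace.x)
    y = np.interp(t_new, trace.time, trace.y)
    # fractional position on the source grid -> bracketing source samples
    pos = (t_new - t0) * trace.rate
    lo = np.clip(np.floor(pos + TIME_EPS).astype(int), 0, trace.n - 1)
    hi = np.clip(np.ceil(pos - TIME_EPS).astype(int), 0, trace.n - 1)
    valid = trace.valid[lo] & trace.valid[hi]
    return EyeTrace(t_new, x, y, valid, new_rate, dict(trace.meta))


def apply_exclusion_windows(
    trace: EyeTrace, windows: Sequence[Sequence[float]]
) -> EyeTrace:
    """Mask out samples falling inside any of the given closed time windows.

    No samples are deleted; samples with timestamps inside any ``[t0, t1]``
    window (boundaries included) get ``valid=False`` in the returned copy.
    """
    out = trace.copy()
    for w in windows:
        t0, t1 = float(w[0]), float(w[1])
        if t1 < t0:
            raise ValueError(f"window end before start: [{t0}, {t1}]")
        inside = (out.time >= t0 - TIME_EPS) & (out.time <= t1 + TIME_EPS)
        out.valid[inside] = False
    return out


def merge_windows(windows: Sequence[Sequence[float]]) -> list[tuple[float, float]]:
    """Union of closed intervals: sort and merge overlapping/touching windows."""
    ws = sorted((float(a), float(b)) for a, b in windows)
    merged: list[tuple[float, float]] = []
    for a, b in ws:
        if b < a:
            raise ValueError(f"window end before start: [{a}, {b}]")
        if merged and a <= merged[-1][1] + TIME_EPS:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


__all__ = [
    "EyeTrace",
    "VelocityTrace",
    "euclidean_speed",
    "compute_velocity",
    "resample",
    "apply_exclusion_windows",
    "merge_windows",
    "TIME_EPS",
]
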