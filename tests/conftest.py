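"""Shared builders for the test suite (all fixtures are generated in code)."""

from __future__ import annotations

import numpy as np
import pytest

from gazecmp.trace import EyeTrace, VelocityTrace


def make_trace(x, y=None, rate=500.0, valid=None) -> EyeTrace:
    x = np.asarray(x, float)
    n = x.size
    y = np.zeros(n) if y is None else np.asarray(y, float)
    valid = np.ones(n, bool) if valid is None else np.asarray(valid, bool)
    return EyeTrace(np.arange(n) / rate, x, y, valid, rate)


def ramp_trace(slope=10.0, duration=1.0, rate=500.0) -> EyeTrace:
    t = np.arange(int(round(duration * rate)) + 1) / rate
    return EyeTrace(t, slope * t, np.zeros_like(t), np.ones_like(t, bool), rate)


def speed_velocity_trace(speeds, rate=500.0, valid=None,
                         accel=None) -> tuple[EyeTrace, VelocityTrace]:
    """A trace/velocity pair with a prescribed horizontal speed sequence.

    Positions are the cumulative integral of the speeds so amplitudes are
    positive; acceleration defaults to zero (the velocity criterion alone is
    under test unless an explicit accel array is passed).
    """
    speeds = np.asarray(speeds, float)
    n = speeds.size
    t = np.arange(n) / rate
    x = np.concatenate(([0.0], np.cumsum(speeds[:-1]) / rate)) if n else np.zeros(0)
    valid = np.ones(n, bool) if valid is None else np.asarray(valid, bool)
    trace = EyeTrace(t, x, np.zeros(n), valid, rate)
    vel = VelocityTrace(
        time=t, vx=speeds.copy(), vy=np.zeros(n), speed=speeds.copy(),
        accel=np.zeros(n) if accel is None else np.asarray(accel, float),
        valid=valid.copy(), rate=rate,
    )
    return trace, vel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
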