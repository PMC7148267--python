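"""Small visual-angle and timing helpers for the experimental geometry."""

from __future__ import annotations

import numpy as np


def screen_subtense_deg(
    width_m: float, height_m: float, distance_m: float
) -> tuple[float, float]:
    """Visual angle subtended by a flat screen viewed head-on at its center.

    Returns (horizontal, vertical) subtense in degrees:
    ``2*atan(extent / (2*distance))`` per axis.
    """
    if distance_m <= 0:
        raise ValueError("viewing distance must be positive")
    h = 2.0 * np.degrees(np.arctan(width_m / (2.0 * distance_m)))
    v = 2.0 * np.degrees(np.arctan(height_m / (2.0 * distance_m)))
    return float(h), float(v)


def samples_in_duration(duration_s: float, rate_hz: float) -> int:
    """Number of sample periods spanned by an interval of given duration."""
    if duration_s < 0 or rate_hz <= 0:
        raise ValueError("duration must be >= 0 and rate positive")
    return int(round(duration_s * rate_hz))


def frames_duration_ms(n_frames: int, refresh_hz: float) -> float:
    """Duration of ``n_frames`` video frames at a given refresh rate, in ms."""
    if n_frames < 0 or refresh_hz <= 0:
        raise ValueError("frame count must be >= 0 and refresh rate positive")
    return 1000.0 * n_frames / refresh_hz


__all__ = ["screen_subtense_deg", "samples_in_duration", "frames_duration_ms"]
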