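"""Plain-text trace files and run configuration.

A trial is stored as a CSV with header ``time_s,x_deg,y_deg,valid``
(``valid`` in {0,1}) plus a sidecar JSON carrying at least ``subject``,
``trial``, ``system``, ``paradigm`` and ``rate_hz``.  All quantities are in
degrees and seconds at this boundary.  Only diff-able text formats are used;
no binary vendor formats.

Clock alignment between the stimulus and tracker timelines is modeled as a
single per-trial offset (``clock_offset_s`` in the sidecar, default 0),
applied to the time column on read.  Trials whose sidecar marks
``aligned: false`` are excluded from pipeline analysis, mirroring a
trigger-validation step in which only trials with a confirmed common time
reference are analyzed further.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trace import EyeTrace

TRACE_COLUMNS = ["time_s", "x_deg", "y_deg", "valid"]

#: default per-system synthesis/analysis parameters: sampling rate, default
#: detector rule, and the between-subject calibration-offset distribution
#: (magnitude mean/SD of the central offset, deg, and the linear vertical
#: field coefficient mean/SD emulating a hemifield-asymmetric error pattern,
#: with opposite signs for the two systems).
DEFAULT_SYSTEMS: dict = {
    "elii-like": {
        "rate": 500.0,
        "detector": "vel_acc",
        "offset_mag_mean": 0.45,
        "offset_mag_sd": 0.12,
        "hemifield_coeff_mean": 0.004,
        "hemifield_coeff_sd": 0.002,
    },
    "esc-like": {
        "rate": 230.0,
        "detector": "run",
        "offset_mag_mean": 1.20,
        "offset_mag_sd": 0.50,
        "hemifield_coeff_mean": -0.012,
        "hemifield_coeff_sd": 0.006,
    },
}


class TraceFormatError(ValueError):
    """Raised for malformed trace files; message includes the offending line."""


def sidecar_path(path: Path | str) -> Path:
    return Path(path).with_suffix(".json")


def write_trace(trace: EyeTrace, path: Path | str) -> Path:
    """Write a trace CSV and its metadata sidecar; returns the CSV path."""
    path = Path(path)
    df = pd.DataFrame({
        "time_s": trace.time,
        "x_deg": trace.x,
        "y_deg": trace.y,
        "valid": trace.valid.astype(int),
    })
    df.to_csv(path, index=False, float_format="%.12g")
    meta = {"rate_hz": trace.rate}
    meta.update(trace.meta)
    with open(sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1, default=str)
    return path


def read_trace(path: Path | str) -> EyeTrace:
    """Read a trace CSV plus sidecar back into an :class:`EyeTrace`.

    Rejects missing columns, non-{0,1} validity values and non-monotone time
    (with the offending line number), a missing sidecar, and a sampling-rate
    mismatch between the data grid and the sidecar's ``rate_hz``.
    """
    path = Path(path)
    sp = sidecar_path(path)
    if not sp.exists():
        raise TraceFormatError(f"{path}: missing metadata sidecar {sp.name}")
    with open(sp) as fh:
        meta = json.load(fh)
    if "rate_hz" not in meta:
        raise TraceFormatError(f"{sp}: sidecar lacks 'rate_hz'")
    rate = float(meta["rate_hz"])

    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise TraceFormatError(f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing column(s) {missing}")

    vals = df["valid"].to_numpy()
    bad = ~np.isin(vals, (0, 1))
    if bad.any():
        line = int(np.argmax(bad)) + 2  # header is line 1
        raise TraceFormatError(
            f"{path}:{line}: valid must be 0 or 1, got {vals[np.argmax(bad)]!r}"
        )
    time = df["time_s"].to_numpy(float)
    steps = np.diff(time)
    if (steps <= 0).any():
        line = int(np.argmax(steps <= 0)) + 3  # second row of the bad pair
        raise TraceFormatError(f"{path}:{line}: time_s not strictly increasing")
    if time.size >= 2:
        med_dt = float(np.median(steps))
        if abs(med_dt * rate - 1.0) > 1e-6:
            raise TraceFormatError(
                f"{path}: data step {med_dt:g} s does not match sidecar "
                f"rate {rate:g} Hz"
            )
    offset = float(meta.get("clock_offset_s", 0.0))
    tmeta = {k: v for k, v in meta.items() if k not in ("rate_hz", "clock_offset_s")}
    tmeta["rate_hz"] = rate
    return EyeTrace(
        time + offset,
        df["x_deg"].to_numpy(float),
        df["y_deg"].to_numpy(float),
        vals.astype(bool),
        rate,
        tmeta,
    )


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; round-trips losslessly via YAML."""

    seed: int = 0
    out_dir: str | None = None
    n_subjects: int = 8
    trials_per_direction: int = 3
    pursuit_trials: int = 4
    paradigms: tuple = ("saccade", "step_ramp", "circular")
    systems: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_SYSTEMS))
    sim: dict = field(default_factory=dict)       # SimulationConfig overrides
    detector: dict = field(default_factory=dict)  # DetectorConfig overrides
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        if "paradigms" in d:
            d["paradigms"] = tuple(d["paradigms"])
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "n_subjects": self.n_subjects,
            "trials_per_direction": self.trials_per_direction,
            "pursuit_trials": self.pursuit_trials,
            "paradigms": list(self.paradigms),
            "systems": copy.deepcopy(self.systems),
            "sim": dict(self.sim),
            "detector": dict(self.detector),
            "log_level": self.log_level,
        }

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


__all__ = [
    "TRACE_COLUMNS",
    "DEFAULT_SYSTEMS",
    "TraceFormatError",
    "write_trace",
    "read_trace",
    "sidecar_path",
    "RunConfig",
]
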