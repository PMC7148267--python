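"""End-to-end composition: simulate -> detect -> metrics -> statistics.

This module wires the stages together the way the full analysis runs:
simulate (or read) gaze traces, differentiate, detect blinks and mask the
standard 40/60 ms exclusion windows around them, detect saccades with the
configured rule, then compute fixation-error and pursuit-gain metrics and
feed the subject-by-condition-by-system tables to the statistics layer.

Numerical choices made here (documented in the methods note):

* the liberal velocity-or-acceleration detector runs on lightly smoothed
  velocity (Savitzky-Golay, 22 ms window) because its 30 deg/s threshold
  sits inside the raw differentiation noise of a trace with realistic
  position noise; the conservative run rule runs on raw velocity, which is
  exactly the robustness it was designed for;
* pursuit gain uses a 100 ms Savitzky-Golay velocity estimate, and the
  steady-state window is shortened by half that support so the smoother
  never straddles the pursuit-segment boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import detect as det
from . import fixation as fx
from . import pursuit as pu
from . import stats as st
from .io import DEFAULT_SYSTEMS, RunConfig
from .simulate import (
    CalibrationField,
    SimulationConfig,
    TargetTrajectory,
    make_circular,
    make_saccade_task,
    make_step_ramp,
    simulate_trace,
)
from .trace import EyeTrace, apply_exclusion_windows, compute_velocity

log = logging.getLogger(__name__)

#: Savitzky-Golay support for detection (liberal rule) and gain estimation (s)
DETECTION_SMOOTH_S = 0.022
GAIN_SMOOTH_S = 0.100


def _odd_window(seconds: float, rate: float) -> int:
    w = int(round(seconds * rate))
    w = max(w, 5)
    return w + 1 if w % 2 == 0 else w


def detector_config_for(name: str, overrides: dict | None = None) -> det.DetectorConfig:
    """Build a detector config by short name ('run'/'esc' or 'vel_acc'/'elii')."""
    if name in ("run", "esc"):
        cfg = det.esc_detector_config()
    elif name in ("vel_acc", "elii"):
        cfg = det.elii_detector_config()
    else:
        raise ValueError(f"unknown detector {name!r}")
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


@dataclass
class TrialEvents:
    """Masked trace, velocity, and detected events of one trial."""

    trace: EyeTrace
    velocity: object
    saccades: list
    blinks: list
    exclusion_windows: list


def detect_events(
    trace: EyeTrace,
    detector: det.DetectorConfig,
    smooth_window: int | None = None,
) -> TrialEvents:
    """Blink masking plus saccade detection on one trace.

    Blinks are found first, the 40/60 ms exclusion windows around them are
    masked, and saccades are then detected on the masked trace.  The liberal
    velocity-or-acceleration rule gets a light Savitzky-Golay smoothing by
    default; the run rule runs on raw velocity.
    """
    blinks = det.detect_blinks(trace)
    windows = det.blink_exclusion_windows(
        blinks, (float(trace.time[0]), float(trace.time[-1]))
    )
    masked = apply_exclusion_windows(trace, windows)
    if smooth_window is None and detector.rule == det.RULE_VEL_ACC:
        smooth_window = _odd_window(DETECTION_SMOOTH_S, trace.rate)
    vel = compute_velocity(masked, smooth_window=smooth_window)
    saccades = det.detect_saccades(masked, vel, detector)
    return TrialEvents(masked, vel, saccades, blinks, windows)


# ---------------------------------------------------------------------------
# per-trial analyses
# ---------------------------------------------------------------------------

def analyze_fixation_trial(
    trace: EyeTrace,
    trajectory: TargetTrajectory,
    detector: det.DetectorConfig,
) -> list[dict]:
    """Fixation-error records of one saccade-task trial (see fixation module)."""
    ev = detect_events(trace, detector)
    return fx.fixation_errors_for_trial(ev.trace, ev.saccades, trajectory)


def analyze_pursuit_trial(
    trace: EyeTrace,
    trajectory: TargetTrajectory,
    detector: det.DetectorConfig,
) -> pu.PursuitTrialMetrics:
    """Steady-state pursuit gain of one step-ramp or circular trial."""
    ev = detect_events(trace, detector)
    seg = trajectory.pursuit_segments()[0]
    paradigm = "linear" if seg.label == "ramp" else "circular"
    window = pu.steady_state_window(
        seg.t0, seg.t1, ev.saccades, edge_margin_s=GAIN_SMOOTH_S / 2.0
    )
    kept = pu.exclude_catchup(window, ev.saccades)
    n_excl = len(ev.saccades)
    kept_s = pu.kept_duration(kept)
    condition = str(trajectory.meta.get("direction",
                    trajectory.meta.get("phase0_rad", "")))
    if window.empty or kept_s < pu.MIN_KEPT_S:
        return pu.PursuitTrialMetrics(paradigm, condition, None, None,
                                      n_excl, kept_s, True)
    vel = compute_velocity(
        ev.trace, smooth_window=_odd_window(GAIN_SMOOTH_S, trace.rate)
    )
    speed = float(seg.params["speed"])
    if paradigm == "linear":
        gain = pu.velocity_gain_linear(vel, kept, speed)
        comp = None
    else:
        dt = 1.0 / trajectory.rate
        res = pu.velocity_gain_circular(
            vel, kept,
            np.gradient(trajectory.tx, dt), np.gradient(trajectory.ty, dt),
            speed,
        )
        gain, comp = (None, None) if res is None else res
    return pu.PursuitTrialMetrics(
        paradigm, condition, gain, comp, n_excl, kept_s,
        flagged=gain is None or window.flagged,
    )


# ---------------------------------------------------------------------------
# parameter-recovery experiments
# ---------------------------------------------------------------------------

def pursuit_gain_experiment(
    true_gain: float,
    n_trials: int = 20,
    rate: float = 500.0,
    seed: int = 0,
    noise_sd: float = 0.05,
    paradigm: str = "step_ramp",
) -> list[float]:
    """Recover a known pursuit gain from simulated trials.

    Simulates ``n_trials`` pursuit trials at the given true gain with white
    position noise of ``noise_sd`` (no drift or blinks, isolating that noise
    source) and returns the per-trial recovered gains of the unflagged
    trials.  Analysis uses the liberal velocity-or-acceleration detector:
    catch-up saccades of ~1 deg peak below 100 deg/s, so the conservative
    run rule cannot see (and hence cannot exclude) them, which inflates the
    gain at low true gains -- the very mechanism by which a high-threshold
    detector biases pursuit gain upward.
    """
    cfg = SimulationConfig(
        rate=rate, pursuit_gain=true_gain, fixation_noise_sd=noise_sd,
        drift_rate_sd=0.0, blink_rate=0.0, seed=seed,
    )
    maker = make_step_ramp if paradigm == "step_ramp" else make_circular
    trajs = maker(n_trials, rate, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    detector = detector_config_for("vel_acc")
    gains = []
    for traj in trajs:
        trace, _ = simulate_trace(traj, cfg, rng)
        m = analyze_pursuit_trial(trace, traj, detector)
        if not m.flagged and m.gain is not None:
            gains.append(m.gain)
    return gains


def fixation_error_experiment(
    offset: tuple[float, float],
    n_trials: int = 20,
    rate: float = 500.0,
    seed: int = 0,
    noise_sd: float = 0.05,
) -> float:
    """Recover a known constant calibration offset from fixation errors.

    Injects a spatially constant offset field, simulates ``n_trials``
    saccade-task trials with white position noise only, and returns the mean
    recovered absolute fixation error over the eccentric targets; this should
    approach the injected offset magnitude.
    """
    cfg = SimulationConfig(
        rate=rate, distortion=CalibrationField.constant(*offset),
        fixation_noise_sd=noise_sd, drift_rate_sd=0.0, blink_rate=0.0,
        seed=seed,
    )
    trajs = make_saccade_task(n_trials, rate, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    detector = detector_config_for("run")
    errs = []
    for traj in trajs:
        trace, _ = simulate_trace(traj, cfg, rng)
        for rec in analyze_fixation_trial(trace, traj, detector):
            if rec["position"].startswith("P") and not rec["flagged"]:
                errs.append(rec["error_deg"])
    if not errs:
        raise RuntimeError("no usable eccentric fixation periods recovered")
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def sample_calibration_field(
    rng: np.random.Generator, system_spec: dict
) -> CalibrationField:
    """Draw one subject's calibration-offset field for a system.

    The central offset has a random direction and a magnitude drawn from the
    system's |Normal(mean, sd)|; a linear vertical field term (opposite mean
    sign per system) adds the hemifield-asymmetric error pattern.
    """
    mag = abs(rng.normal(system_spec["offset_mag_mean"],
                         system_spec["offset_mag_sd"]))
    ang = rng.uniform(0.0, 2.0 * math.pi)
    coeff = rng.normal(system_spec.get("hemifield_coeff_mean", 0.0),
                       system_spec.get("hemifield_coeff_sd", 0.0))
    f = CalibrationField()
    f.cx[0] = mag * math.cos(ang)
    f.cy[0] = mag * math.sin(ang)
    f.cy[2] = coeff  # dy contribution linear in y
    return f


def simulate_cohort(
    n_subjects: int = 8,
    trials_per_direction: int = 3,
    seed: int = 0,
    systems: dict | None = None,
    sim_overrides: dict | None = None,
    detector_overrides: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Saccade-task fixation errors for a subject cohort on both systems.

    Every subject runs the saccade task once per system (each system with its
    own sampling rate, detector and subject-specific calibration-offset
    field).  Returns trial-level records (``subject``, ``system``,
    ``position``, ``trial``, ``error_deg``) for trials whose outward and
    return saccades were both detected, plus a reconciliation dict counting
    simulated, analyzed and flagged trials.
    """
    systems = systems or DEFAULT_SYSTEMS
    ss = np.random.SeedSequence(seed)
    rows = []
    counts = {"simulated": 0, "analyzed": 0, "flagged": 0}
    for sys_name, spec in systems.items():
        detector = detector_config_for(spec.get("detector", "run"),
                                       detector_overrides)
        rate = float(spec["rate"])
        for subj in range(n_subjects):
            rng = np.random.default_rng(ss.spawn(1)[0])
            field = sample_calibration_field(rng, spec)
            overrides = dict(sim_overrides or {})
            cfg = SimulationConfig(rate=rate, distortion=field,
                                   seed=seed, **overrides)
            n_trials = 8 * trials_per_direction
            trajs = make_saccade_task(
                n_trials, rate, seed=int(rng.integers(2 ** 31))
            )
            trial_no = 0
            for traj in trajs:
                trace, _ = simulate_trace(traj, cfg, rng)
                counts["simulated"] += 1
                recs = fx.fixation_errors_for_trial(
                    *_masked_and_saccades(trace, detector), traj
                )
                if any(r["flagged"] for r in recs):
                    counts["flagged"] += 1
                    continue
                counts["analyzed"] += 1
                for r in recs:
                    rows.append({
                        "subject": f"S{subj}",
                        "system": sys_name,
                        "position": r["position"],
                        "trial": trial_no,
                        "error_deg": r["error_deg"],
                    })
                trial_no += 1
    df = pd.DataFrame(rows)
    log.info("cohort: %(simulated)d trials simulated, %(analyzed)d analyzed, "
             "%(flagged)d flagged", counts)
    assert counts["simulated"] == counts["analyzed"] + counts["flagged"]
    return df, counts


def _masked_and_saccades(trace, detector):
    ev = detect_events(trace, detector)
    return ev.trace, ev.saccades


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic study and return its metric and stats tables.

    Stages: simulate cohorts per paradigm -> velocity -> blink masking ->
    saccade detection -> fixation / pursuit metrics -> variability
    decomposition and within-subject tests.  Deterministic given
    ``config.seed``; writes TSV tables to ``config.out_dir`` when set.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    log.info("pipeline seed=%d subjects=%d paradigms=%s",
             config.seed, config.n_subjects, list(config.paradigms))
    out: dict = {"counts": {}}

    if "saccade" in config.paradigms:
        fix_df, counts = simulate_cohort(
            config.n_subjects, config.trials_per_direction, config.seed,
            config.systems, config.sim, config.detector,
        )
        out["fixation"] = fix_df
        out["counts"]["saccade"] = counts
        if not fix_df.empty:
            ecc = fix_df[fix_df["position"].str.startswith("P")]
            out["fixation_summary"] = fx.aggregate_fixation_errors(ecc)
            out["fixation_sd_decomposition"] = st.sd_decomposition(
                ecc.rename(columns={"position": "condition",
                                    "error_deg": "value"})
            )
            wide = (
                ecc.groupby(["subject", "system"])["error_deg"].mean()
                .unstack("system")
            )
            if wide.shape[1] == 2 and not wide.isna().any().any():
                out["fixation_anova"] = st.rm_anova_oneway(wide.to_numpy())

    pursuit_rows = []
    ss = np.random.SeedSequence([config.seed, 101])
    for paradigm in ("step_ramp", "circular"):
        if paradigm not in config.paradigms:
            continue
        maker = make_step_ramp if paradigm == "step_ramp" else make_circular
        for sys_name, spec in config.systems.items():
            detector = detector_config_for(spec.get("detector", "run"),
                                           config.detector)
            rate = float(spec["rate"])
            for subj in range(config.n_subjects):
                rng = np.random.default_rng(ss.spawn(1)[0])
                overrides = dict(config.sim)
                overrides.setdefault(
                    "pursuit_gain", float(np.clip(rng.normal(0.92, 0.05),
                                                  0.7, 1.05))
                )
                cfg = SimulationConfig(rate=rate, seed=config.seed, **overrides)
                trajs = maker(config.pursuit_trials, rate,
                              seed=int(rng.integers(2 ** 31)))
                n_flagged = 0
                for k, traj in enumerate(trajs):
                    trace, _ = simulate_trace(traj, cfg, rng)
                    m = analyze_pursuit_trial(trace, traj, detector)
                    if m.flagged or m.gain is None:
                        n_flagged += 1
                        continue
                    pursuit_rows.append({
                        "subject": f"S{subj}",
                        "system": sys_name,
                        "paradigm": m.paradigm,
                        "condition": m.condition,
                        "trial": k,
                        "gain": m.gain,
                        "gain_x": m.component_gains[0] if m.component_gains else np.nan,
                        "gain_y": m.component_gains[1] if m.component_gains else np.nan,
                        "n_excluded": m.n_excluded_segments,
                    })
                out["counts"].setdefault(paradigm, {"simulated": 0, "flagged": 0})
                out["counts"][paradigm]["simulated"] += len(trajs)
                out["counts"][paradigm]["flagged"] += n_flagged
    if pursuit_rows:
        pdf = pd.DataFrame(pursuit_rows)
        out["pursuit"] = pdf
        lin = pdf[pdf["paradigm"] == "linear"]
        if not lin.empty:
            try:
                out["pursuit_sd_decomposition"] = st.sd_decomposition(
                    lin.rename(columns={"gain": "value"})
                )
            except ValueError as exc:  # < 2 trials per direction cell
                log.warning("pursuit SD decomposition skipped: %s", exc)
        circ = pdf[pdf["paradigm"] == "circular"]
        wide = circ.groupby(["subject", "system"])["gain"].mean().unstack("system")
        if wide.shape[1] == 2 and not wide.isna().any().any():
            cols = list(wide.columns)
            out["circular_gain_ttest"] = st.paired_t(
                wide[cols[0]].to_numpy(), wide[cols[1]].to_numpy()
            )

    if config.out_dir:
        from pathlib import Path

        outdir = Path(config.out_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key in ("fixation", "fixation_summary", "fixation_sd_decomposition",
                    "pursuit", "pursuit_sd_decomposition"):
            if key in out and isinstance(out[key], pd.DataFrame):
                out[key].to_csv(outdir / f"{key}.tsv", sep="\t", index=False)
        log.info("tables written to %s", outdir)
    return out


__all__ = [
    "DETECTION_SMOOTH_S",
    "GAIN_SMOOTH_S",
    "detector_config_for",
    "detect_events",
    "TrialEvents",
    "analyze_fixation_trial",
    "analyze_pursuit_trial",
    "pursuit_gain_experiment",
    "fixation_error_experiment",
    "sample_calibration_field",
    "simulate_cohort",
    "run_pipeline",
]
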