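"""Per-session processing: from raw trials to the aligned, normalized
matrices every downstream analysis consumes.

One neuron per session.  Processing order: velocity estimation -> movement
detection -> BREM template -> embedded-saccade detection on blink trials ->
inclusion filtering -> kinematic variables -> spike densities (3 ms kernel
for correlation/threshold work, 10 ms for rate estimation) -> normalization
by the peak trial-averaged control rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import kinematics as kin
from . import preprocess as pp
from .containers import Session, TrialRecord
from .kinematics import BREMTemplate, EmbeddedSaccadeOnset, InclusionResult

log = logging.getLogger(__name__)

KERNEL_CORRELATION = 3.0  # ms; across-trial correlation and threshold analyses
KERNEL_RATE = 10.0  # ms; accumulation-rate analysis
NORM_WINDOW = (-100.0, 150.0)  # ms re saccade onset, for the peak normalizer


@dataclass
class ProcessedTrial:
    """One trial after velocity estimation and event detection."""

    trial: TrialRecord
    h_vel: np.ndarray
    v_vel: np.ndarray
    saccade_onset: Optional[float] = None  # ms; velocity-criterion crossing
    # (control: raw velocity; blink: BREM-subtracted residual at/after the
    # detected embedded-saccade onset)
    movement_onset: Optional[float] = None  # blink trials: overall movement onset
    movement_offset: Optional[float] = None
    embedded: Optional[EmbeddedSaccadeOnset] = None
    kinematic_series: Optional[np.ndarray] = None  # goal-projected (residual) velocity
    endpoint: Optional[tuple[float, float]] = None


@dataclass
class ProcessedSession:
    session: Session
    dt: float
    goal_direction: float  # deg, fixation -> target
    template: Optional[BREMTemplate]
    control: list[ProcessedTrial] = field(default_factory=list)
    blink: list[ProcessedTrial] = field(default_factory=list)
    inclusion: Optional[InclusionResult] = None
    norm_divisor_corr: float = float("nan")  # peak control rate, 3 ms kernel
    norm_divisor_rate: float = float("nan")  # peak control rate, 10 ms kernel
    densities_corr: dict[int, "pp.SpikeDensity"] = field(default_factory=dict)
    densities_rate: dict[int, "pp.SpikeDensity"] = field(default_factory=dict)

    @property
    def triggered_blink(self) -> list[ProcessedTrial]:
        """Blink trials whose embedded saccade started >= 20 ms after movement onset."""
        return [
            t
            for t in self.blink
            if t.embedded is not None and t.embedded.classification == "triggered"
        ]

    @property
    def detected_blink(self) -> list[ProcessedTrial]:
        return [t for t in self.blink if t.embedded is not None]


def _aligned_onset(
    time: np.ndarray,
    res_h: np.ndarray,
    res_v: np.ndarray,
    embedded_onset: float,
    criterion: float = pp.ONSET_CRITERION,
    max_lookahead_ms: float = 20.0,
) -> float:
    """Alignment onset for a blink trial: the first per-component velocity
    criterion crossing of the BREM-subtracted residual at/after the detected
    embedded-saccade onset.

    The template-bound detector finds the embedded saccade, but its effective
    criterion (2.5 template s.d.) differs from the control detector's fixed
    velocity criterion; aligning rates and kinematics in both conditions on
    the same criterion avoids a condition-specific offset against the steep
    burst rise.  Falls back to the embedded onset when the residual never
    crosses the criterion within the lookahead.
    """
    i0 = int(np.searchsorted(time, embedded_onset))
    i1 = int(np.searchsorted(time, embedded_onset + max_lookahead_ms))
    hit = np.flatnonzero(
        (np.abs(res_h[i0:i1]) >= criterion) | (np.abs(res_v[i0:i1]) >= criterion)
    )
    if len(hit) == 0:
        log.info("residual never crossed the alignment criterion; using the embedded onset")
        return embedded_onset
    return float(time[i0 + hit[0]])


def _endpoint(trial: TrialRecord, tail_ms: float = 50.0) -> tuple[float, float]:
    """Final eye position, averaged over the trial's last `tail_ms`."""
    n = max(1, int(round(tail_ms / trial.eye.dt)))
    return (float(np.mean(trial.eye.h_pos[-n:])), float(np.mean(trial.eye.v_pos[-n:])))


def process_session(
    session: Session,
    variant: str = "projected",
    smooth_sd_ms: float = pp.DEFAULT_SMOOTH_SD_MS,
) -> ProcessedSession:
    """Run detection, template building, and kinematic preparation for one
    session.

    `variant` selects the kinematic variable for blink trials: "projected"
    (BREM-subtracted residual projected on the goal direction, the primary
    analysis) or "raw" (unprojected vectorial residual, the control variant).
    """
    if variant not in ("projected", "raw"):
        raise ValueError(f"unknown kinematic variant {variant!r}")
    dt = session.trials[0].eye.dt if session.trials else 1.0

    # --- goal direction (single target location per session) ----------------
    targets = [t.target for t in session.trials if t.target is not None]
    if targets:
        goal_dir = kin.goal_direction((0.0, 0.0), targets[0])
    else:
        goal_dir = 0.0

    proc = ProcessedSession(session=session, dt=dt, goal_direction=goal_dir, template=None)

    # --- velocities ----------------------------------------------------------
    velocities: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for trial in session.trials:
        trace = pp.compute_velocity(trial.eye, smooth_sd_ms=smooth_sd_ms)
        velocities[trial.trial_id] = (trace.h_vel, trace.v_vel)

    # --- BREM template -------------------------------------------------------
    brem_pairs = []
    for trial in session.brem_trials:
        h_vel, v_vel = velocities[trial.trial_id]
        trace = trial.eye
        ev = pp.detect_movement(
            type(trace)(trace.time, trace.h_pos, trace.v_pos, h_vel, v_vel),
            search_start=trial.blink_on,
        )
        if ev is None:
            log.info("session %s: BREM trial %d below criterion, skipped", session.session_id, trial.trial_id)
            continue
        i_on = int(np.searchsorted(trace.time, ev.onset))
        brem_pairs.append((h_vel[i_on:], v_vel[i_on:]))
    if len(brem_pairs) >= 2:
        proc.template = kin.build_brem_template(brem_pairs, dt=dt)
    elif session.blink_trials:
        log.warning("session %s: <2 BREM trials; blink analyses unavailable", session.session_id)

    # --- spike densities -----------------------------------------------------
    for trial in session.trials:
        t0, t1 = float(trial.eye.time[0]), float(trial.eye.time[-1])
        proc.densities_corr[trial.trial_id] = pp.spike_density(
            trial.spikes, KERNEL_CORRELATION, (t0, t1), dt
        )
        proc.densities_rate[trial.trial_id] = pp.spike_density(
            trial.spikes, KERNEL_RATE, (t0, t1), dt
        )

    # --- control trials ------------------------------------------------------
    for trial in session.control_trials:
        h_vel, v_vel = velocities[trial.trial_id]
        trace = trial.eye
        ev = pp.detect_movement(
            type(trace)(trace.time, trace.h_pos, trace.v_pos, h_vel, v_vel),
            search_start=trial.go_cue,
        )
        pt = ProcessedTrial(trial=trial, h_vel=h_vel, v_vel=v_vel)
        if ev is None:
            log.info("session %s: control trial %d has no movement", session.session_id, trial.trial_id)
        else:
            pt.saccade_onset = ev.onset
            pt.movement_offset = ev.offset
            if variant == "projected":
                pt.kinematic_series = kin.project_on_goal(h_vel, v_vel, goal_dir)
            else:
                pt.kinematic_series = kin.vectorial_velocity(h_vel, v_vel)
            pt.endpoint = _endpoint(trial)
        proc.control.append(pt)

    # --- blink trials --------------------------------------------------------
    for trial in session.blink_trials:
        h_vel, v_vel = velocities[trial.trial_id]
        trace = trial.eye
        pt = ProcessedTrial(trial=trial, h_vel=h_vel, v_vel=v_vel)
        ev = pp.detect_movement(
            type(trace)(trace.time, trace.h_pos, trace.v_pos, h_vel, v_vel),
            search_start=trial.blink_on,
        )
        if ev is not None and proc.template is not None:
            pt.movement_onset = ev.onset
            pt.movement_offset = ev.offset
            i_on = int(np.searchsorted(trace.time, ev.onset))
            emb = kin.detect_embedded_saccade(h_vel[i_on:], v_vel[i_on:], proc.template)
            pt.embedded = emb
            if emb is not None:
                res_h, res_v = np.array(h_vel), np.array(v_vel)
                k = min(len(res_h) - i_on, len(proc.template.mean_h))
                res_h[i_on : i_on + k] -= proc.template.mean_h[:k]
                res_v[i_on : i_on + k] -= proc.template.mean_v[:k]
                pt.saccade_onset = _aligned_onset(
                    trace.time, res_h, res_v, ev.onset + emb.onset_delay
                )
                if variant == "projected":
                    pt.kinematic_series = kin.project_on_goal(res_h, res_v, goal_dir)
                else:
                    pt.kinematic_series = kin.vectorial_velocity(res_h, res_v)
                # the residual kinematic variable only exists once the
                # blink-triggered movement does; earlier samples are missing
                pt.kinematic_series[:i_on] = np.nan
                pt.endpoint = _endpoint(trial)
        proc.blink.append(pt)

    proc.inclusion = kin.apply_inclusion_criteria(
        {t.trial.trial_id: t.embedded for t in proc.blink}
    )

    # --- normalization divisors ---------------------------------------------
    ctrl_ok = [t for t in proc.control if t.saccade_onset is not None]
    if ctrl_ok:
        for attr, dens_map in (
            ("norm_divisor_corr", proc.densities_corr),
            ("norm_divisor_rate", proc.densities_rate),
        ):
            try:
                peak = pp.control_peak_rate(
                    [dens_map[t.trial.trial_id] for t in ctrl_ok],
                    [t.saccade_onset for t in ctrl_ok],
                    NORM_WINDOW,
                    dt,
                )
            except pp.NormalizationError:
                peak = float("nan")
            setattr(proc, attr, peak)
    return proc


# ---------------------------------------------------------------------------
# aligned matrices
# ---------------------------------------------------------------------------

def activity_matrix(
    proc: ProcessedSession,
    trials: list[ProcessedTrial],
    window: tuple[float, float],
    kernel: str = "corr",
    normalized: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Saccade-aligned (trials x times) firing-rate matrix.

    `kernel` is "corr" (3 ms) or "rate" (10 ms); normalization uses the
    control-derived divisor for that kernel (shared across conditions).
    """
    dens_map = proc.densities_corr if kernel == "corr" else proc.densities_rate
    divisor = proc.norm_divisor_corr if kernel == "corr" else proc.norm_divisor_rate
    dens = [dens_map[t.trial.trial_id] for t in trials]
    aligns = [t.saccade_onset for t in trials]
    rel, mat = pp.aligned_rate_matrix(dens, aligns, window, proc.dt)
    if normalized:
        mat = mat / divisor
    return rel, mat


def blink_aligned_rate_matrix(
    proc: ProcessedSession,
    trials: list[ProcessedTrial],
    window: tuple[float, float],
    normalized: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Blink-aligned (trials x times) 10 ms-kernel rate matrix."""
    dens = [proc.densities_rate[t.trial.trial_id] for t in trials]
    aligns = [t.trial.blink_on for t in trials]
    rel, mat = pp.aligned_rate_matrix(dens, aligns, window, proc.dt)
    if normalized:
        mat = mat / proc.norm_divisor_rate
    return rel, mat


def kinematics_matrix(
    proc: ProcessedSession,
    trials: list[ProcessedTrial],
    window: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Saccade-aligned (trials x times) matrix of the kinematic variable."""
    sigs = [t.kinematic_series for t in trials]
    times = [t.trial.eye.time for t in trials]
    aligns = [t.saccade_onset for t in trials]
    return pp.aligned_signal_matrix(sigs, times, aligns, window, proc.dt)
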