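"""Synthetic delayed-saccade sessions with blink perturbations.

The generator emulates the data the analyses expect, with every injected
parameter recorded for recovery tests:

* task structure -- fixation, target onset, a variable 500-1200 ms delay
  period, GO cue, and on perturbation trials an air-puff blink 100-250 ms
  after GO;
* an accumulate-to-criterion initiation model -- a per-trial linear ramp of
  preparatory drive reaches the initiation criterion and the saccade follows
  after a fixed OPN-gate lead.  A blink opens the gate early: the ramp
  accelerates (slope multiplier) and the saccade launches at a configurable
  fraction of the control criterion;
* activity-kinematics coupling -- eye velocity during open-gate epochs is a
  gain-scaled copy of the neuron's drive delayed by the efference delay
  (burst gain during the saccade, a smaller leak gain for pre-saccade
  leakage on blink trials), so across-trial rate variability induces
  velocity variability at the injected lag;
* blink-related eye movements (BREMs) -- loop-like, closed trajectories
  modelled as a difference of two gamma-shaped velocity pulses per component,
  with per-trial gain jitter and smooth additive noise;
* a main-sequence saccade profile -- raised-cosine velocity bell whose peak
  saturates with amplitude, V(A) = vmax * (1 - exp(-A / a0)).

Spikes are drawn from an inhomogeneous Poisson process around the composite
rate (baseline + preparatory ramp + motor burst), and positions are the
integral of velocity plus white measurement noise, so the analysis chain
(velocity estimation, spike-density estimation, detection) runs on the same
kind of raw material it would see in recorded data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import gamma as gamma_dist

from .config import ConfigError, GeneratorConfig
from .containers import (
    BLINK,
    BREM,
    CONTROL,
    EyeTrace,
    GroundTruth,
    Session,
    TrialRecord,
    TrialTruth,
)

# velocity criteria shared with the detection stage (deg/s)
ONSET_CRITERION = 50.0

# BREM template shape parameters: outward and return gamma pulses per
# component (shape k, scale theta in ms, return-pulse onset delay in ms)
_BREM_SHAPE = 3.0
_BREM_OUT_SCALE = 8.0
_BREM_RET_SCALE = 14.0
_BREM_RET_DELAY = 40.0
# fraction of the loop excursion assigned to each (nasal, downward) component
_BREM_COMPONENT_FRACTION = 0.7


# ---------------------------------------------------------------------------
# low-level pieces
# ---------------------------------------------------------------------------

def smooth_unit_noise(rng: np.random.Generator, n: int, smooth_sd_samples: float) -> np.ndarray:
    """Stationary unit-variance Gaussian noise with Gaussian autocorrelation.

    White noise is low-pass filtered with a Gaussian kernel and rescaled by
    the analytic norm of the kernel, so the marginal s.d. is exactly 1
    regardless of the smoothing width.
    """
    white = rng.standard_normal(n)
    if smooth_sd_samples <= 0:
        return white
    smoothed = gaussian_filter1d(white, smooth_sd_samples, mode="reflect")
    impulse = np.zeros(int(8 * smooth_sd_samples) * 2 + 1)
    impulse[len(impulse) // 2] = 1.0
    kernel = gaussian_filter1d(impulse, smooth_sd_samples)
    norm = math.sqrt(float(np.sum(kernel**2)))
    return smoothed / norm


def main_sequence_peak_velocity(amplitude: float, vmax: float, a0: float) -> float:
    """Saturating amplitude / peak-velocity relation V(A) = vmax (1 - e^(-A/a0))."""
    return vmax * (1.0 - math.exp(-amplitude / a0))


def saccade_profile(time: np.ndarray, onset: float, amplitude: float, vmax: float, a0: float) -> tuple[np.ndarray, float, float]:
    """Skewed velocity bell for a saccade of given amplitude.

    The profile v(x) ~ x (1 - x)^2 (x = normalized time) rises steeply,
    peaks in the first third of the movement, and decelerates slowly --
    the stereotypical saccadic waveform.  Duration is set so the profile
    integrates to the amplitude.  Returns (velocity magnitude over `time`,
    peak velocity, duration in ms).
    """
    vp = main_sequence_peak_velocity(amplitude, vmax, a0)
    # v(x) = k x (1-x)^2 on x in [0, 1]: integral k/12, peak 4k/27 at x = 1/3
    duration = 16000.0 * amplitude / (9.0 * vp)  # ms
    k = 27.0 * vp / 4.0
    x = np.clip((time - onset) / duration, 0.0, 1.0)
    bell = k * x * (1.0 - x) ** 2
    bell[(time < onset) | (time > onset + duration)] = 0.0
    return bell, vp, duration


def brem_template_mean(config: GeneratorConfig, time: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic BREM velocity template (time, horizontal, vertical).

    Each component is a difference of two unit-area gamma pulses (outward then
    return), so the displacement loop closes by construction.  The outward
    excursion is nasal (negative horizontal) and downward (negative vertical).
    """
    if time is None:
        time = np.arange(0.0, config.brem_duration, config.dt)
    out = gamma_dist.pdf(time, a=_BREM_SHAPE, scale=_BREM_OUT_SCALE)
    ret = gamma_dist.pdf(time - _BREM_RET_DELAY, a=_BREM_SHAPE, scale=_BREM_RET_SCALE)
    base = out - ret  # per-ms rate of displacement; integral ~ 0
    excursion = -_BREM_COMPONENT_FRACTION * config.brem_amplitude_mean
    vel = excursion * base * 1000.0  # deg/s
    return time, vel.copy(), vel.copy()


def generate_brem_velocity(config: GeneratorConfig, rng: np.random.Generator) -> EyeTrace:
    """One BREM velocity draw: template x gain jitter + smooth, zero-integral noise."""
    time, mh, mv = brem_template_mean(config)
    gain = 1.0 + config.brem_gain_sd * rng.standard_normal()
    smooth_samples = config.brem_noise_smooth_ms / config.dt
    traces = []
    for mean_component in (mh, mv):
        noise = config.brem_noise_sd * smooth_unit_noise(rng, len(time), smooth_samples)
        noise -= noise.mean()  # loop closure: the noise adds zero net displacement
        traces.append(gain * mean_component + noise)
    vh, vv = traces
    dt_s = config.dt / 1000.0
    return EyeTrace(
        time=time,
        h_pos=np.cumsum(vh) * dt_s,
        v_pos=np.cumsum(vv) * dt_s,
        h_vel=vh,
        v_vel=vv,
    )


def _poisson_spikes(rng: np.random.Generator, rate: np.ndarray, time: np.ndarray, dt: float) -> np.ndarray:
    """Inhomogeneous Poisson spike times from a rate (spikes/s) on a ms grid."""
    counts = rng.poisson(rate * dt / 1000.0)
    idx = np.repeat(np.arange(len(time)), counts)
    if len(idx) == 0:
        return np.empty(0)
    # bins are centered on the grid times so spike timing is unbiased
    # relative to the rate curve
    return np.sort(time[idx] + rng.uniform(-0.5 * dt, 0.5 * dt, size=len(idx)))


def _component_onset(vh: np.ndarray, vv: np.ndarray, time: np.ndarray, criterion: float = ONSET_CRITERION) -> float | None:
    """Earliest per-component velocity-criterion crossing (the detector's min rule)."""
    onsets = []
    for v in (vh, vv):
        above = np.flatnonzero(np.abs(v) >= criterion)
        if len(above):
            onsets.append(time[above[0]])
    return min(onsets) if onsets else None


def _integrate(vel: np.ndarray, dt_s: float) -> np.ndarray:
    """Trapezoid cumulative integral: position at the grid times themselves,
    so centrally differenced velocity is not shifted by half a sample."""
    return (np.cumsum(vel) - 0.5 * vel - 0.5 * vel[0]) * dt_s


def _drift_velocity(config: GeneratorConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Slow fixational drift as the derivative of bounded smooth position
    noise (deg/s); the position excursion stays within ~drift_pos_sd."""
    pos = config.drift_pos_sd * smooth_unit_noise(rng, n, config.drift_smooth_ms / config.dt)
    return np.gradient(pos) * config.sampling_rate


def _shift_forward(x: np.ndarray, samples: int) -> np.ndarray:
    """Delay a signal by `samples`, zero-padding the front."""
    out = np.zeros_like(x)
    if samples < len(x):
        out[samples:] = x[: len(x) - samples]
    return out


@dataclass
class _TrialDraws:
    """Per-trial latent variables shared by control and blink construction."""

    q: float  # preparatory rate scale
    slope: float  # base accumulation slope, spikes/s/ms (before q)
    burst_gain_jitter: float
    direction_jitter: float  # deg


def _draw_trial_latents(config: GeneratorConfig, rng: np.random.Generator) -> _TrialDraws:
    q = float(np.exp(config.rate_scale_sd * rng.standard_normal()))
    if config.rt_mean is not None:
        rt = max(rng.normal(config.rt_mean, config.rt_sd), config.opn_lead + 60.0)
        slope = config.threshold_rate / (rt - config.opn_lead) / q
    else:
        slope = max(rng.normal(config.prep_slope_mean, config.prep_slope_sd), 0.3)
    return _TrialDraws(
        q=q,
        slope=float(slope),
        burst_gain_jitter=1.0 + config.burst_gain_jitter_sd * rng.standard_normal(),
        direction_jitter=config.saccade_direction_jitter * rng.standard_normal(),
    )


def _rotate(vec: np.ndarray, degrees: float) -> np.ndarray:
    th = math.radians(degrees)
    c, s = math.cos(th), math.sin(th)
    return np.array([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1]])


# ---------------------------------------------------------------------------
# trial generators
# ---------------------------------------------------------------------------

def _target_vector(config: GeneratorConfig) -> np.ndarray:
    th = math.radians(config.target_direction)
    return config.target_eccentricity * np.array([math.cos(th), math.sin(th)])


def _build_ramp(time: np.ndarray, go: float, slope: float, cap: float, taper_start: float, taper_ms: float = 50.0) -> np.ndarray:
    """Linear preparatory ramp after GO, capped at the crossing level, tapering
    back toward zero after the burst ends."""
    ramp = np.clip(slope * (time - go), 0.0, cap)
    fade = np.clip(1.0 - (time - taper_start) / taper_ms, 0.0, 1.0)
    return ramp * fade


def _build_blink_ramp(time: np.ndarray, go: float, blink: float, slope: float, multiplier: float, cap: float, taper_start: float, taper_ms: float = 50.0) -> np.ndarray:
    """Ramp with post-blink slope acceleration, capped at the trigger level."""
    pre = slope * (time - go)
    level_at_blink = slope * (blink - go)
    post = level_at_blink + multiplier * slope * (time - blink)
    ramp = np.where(time <= blink, pre, post)
    ramp = np.clip(ramp, 0.0, cap)
    fade = np.clip(1.0 - (time - taper_start) / taper_ms, 0.0, 1.0)
    return ramp * fade


def generate_control_trial(config: GeneratorConfig, rng: np.random.Generator, trial_id: int = 0) -> tuple[TrialRecord, TrialTruth]:
    """One control delayed-saccade trial.

    Events are ordered fixation < target < GO < saccade.  The saccade is
    triggered when the (noise-free) accumulator q*slope*(t - GO) reaches the
    initiation criterion; the movement follows after the OPN-gate lead.  Eye
    velocity during the movement equals burst_gain x motor drive delayed by
    the efference delay, so rate variability maps onto velocity variability
    at the injected lag.
    """
    dt = config.dt
    draws = _draw_trial_latents(config, rng)
    go = config.target_onset + rng.uniform(*config.delay_range)
    go = round(go / dt) * dt

    eff_slope = draws.q * draws.slope  # true accumulation slope, spikes/s/ms
    t_cross = go + config.threshold_rate / eff_slope
    profile_start = t_cross + config.opn_lead
    gate_open = profile_start - config.opn_lead  # OPN pause at criterion crossing

    target = _target_vector(config)
    aim = _rotate(target, draws.direction_jitter)
    amplitude = float(np.hypot(*aim))
    u_aim = aim / amplitude

    d_samples = int(round(config.efference_delay / dt))
    _, _, duration = saccade_profile(np.array([0.0]), 0.0, amplitude, config.vmax, config.a0)
    t_end = profile_start + duration + 200.0
    time = np.arange(0.0, t_end, dt)

    burst_start = profile_start - config.efference_delay
    bell, _, duration = saccade_profile(time, burst_start, amplitude, config.vmax, config.a0)
    burst = bell / config.burst_gain  # spikes/s so that velocity = gain * rate

    ramp = _build_ramp(time, go, draws.slope, config.threshold_rate / draws.q, burst_start + duration)
    eta = smooth_unit_noise(rng, len(time), config.rate_noise_smooth_ms / dt)
    prep = draws.q * ramp * (1.0 + config.rate_noise_sd * eta)
    motor = draws.burst_gain_jitter * burst * (1.0 + config.burst_noise_sd * eta)
    rate = np.clip(config.baseline_rate + prep + motor, 0.0, None)
    spikes = _poisson_spikes(rng, rate, time, dt)

    vel_mag = config.burst_gain * _shift_forward(motor, d_samples)
    vh = vel_mag * u_aim[0] + _drift_velocity(config, rng, len(time))
    vv = vel_mag * u_aim[1] + _drift_velocity(config, rng, len(time))

    # ground-truth onset: the detector's velocity criterion applied to the
    # noise-free saccadic profile components
    clean_mag = config.burst_gain * _shift_forward(draws.burst_gain_jitter * burst, d_samples)
    true_onset = _component_onset(clean_mag * u_aim[0], clean_mag * u_aim[1], time)

    dt_s = dt / 1000.0
    noise = config.position_noise_sd
    eye = EyeTrace(
        time=time,
        h_pos=_integrate(vh, dt_s) + noise * rng.standard_normal(len(time)),
        v_pos=_integrate(vv, dt_s) + noise * rng.standard_normal(len(time)),
    )
    trial = TrialRecord(
        trial_id=trial_id,
        condition=CONTROL,
        target=(float(target[0]), float(target[1])),
        eye=eye,
        spikes=spikes,
        target_on=config.target_onset,
        go_cue=go,
    )
    truth = TrialTruth(
        trial_id=trial_id,
        condition=CONTROL,
        rate_scale=draws.q,
        slope_pre=eff_slope,
        slope_post=eff_slope,
        gate_open=gate_open,
        saccade_onset=true_onset,
        profile_start=profile_start,
        reaction_time=profile_start - go,
    )
    return trial, truth


def generate_blink_trial(config: GeneratorConfig, rng: np.random.Generator, trial_id: int = 0) -> tuple[TrialRecord, TrialTruth]:
    """One blink-perturbation trial.

    The blink opens the gate at a random time 100-250 ms after GO.  From then
    on the eye carries a BREM draw plus leak_gain x delayed preparatory drive;
    the accumulator accelerates (slope multiplier) and triggers the saccade at
    blink_threshold_fraction x the control criterion.  The saccadic profile is
    aimed so the eventual endpoint compensates for the BREM loop and expected
    leak drift, emulating the preserved endpoint accuracy of blink-triggered
    saccades.
    """
    dt = config.dt
    go = config.target_onset + rng.uniform(*config.delay_range)
    go = round(go / dt) * dt
    blink = go + rng.uniform(*config.blink_window)
    blink = round(blink / dt) * dt

    # resample latents until the natural saccade would not have pre-empted the
    # blink (movements already in flight at blink time are a different
    # phenomenon and were excluded from the recorded datasets)
    for _ in range(200):
        draws = _draw_trial_latents(config, rng)
        eff_slope = draws.q * draws.slope
        t_nat = go + config.threshold_rate / eff_slope + config.opn_lead
        if t_nat > blink + 5.0:
            break

    frac = config.blink_threshold_fraction
    mult = config.post_blink_slope_multiplier
    level_at_blink = eff_slope * (blink - go)
    trigger_level = frac * config.threshold_rate
    if level_at_blink >= trigger_level:
        t_cross = blink
        trigger_level = level_at_blink
    else:
        t_cross = blink + (trigger_level - level_at_blink) / (mult * eff_slope)
    profile_start = min(t_cross + config.efference_delay, t_nat)
    profile_start = max(profile_start, blink + 2.0)

    brem = generate_brem_velocity(config, rng)
    target = _target_vector(config)
    u_goal = target / np.linalg.norm(target)
    d_samples = int(round(config.efference_delay / dt))

    # --- aim the saccade so the endpoint compensates for BREM + leak drift ---
    dt_s = dt / 1000.0
    n_pre = int(round((profile_start - blink) / dt))
    n_pre = min(n_pre, len(brem.time))
    brem_drift = np.array([
        float(np.sum(brem.h_vel[:n_pre])) * dt_s,
        float(np.sum(brem.v_vel[:n_pre])) * dt_s,
    ])
    brem_remaining = -brem_drift  # the loop closes: remaining integral is minus the drift
    leak_drift_pre = config.leak_gain * trigger_level * 0.5 * (profile_start - blink) / 1000.0
    aim0 = target - brem_drift - brem_remaining - leak_drift_pre * u_goal
    amp0 = float(np.hypot(*aim0))
    _, _, duration = saccade_profile(np.array([0.0]), 0.0, amp0, config.vmax, config.a0)
    leak_drift_sacc = config.leak_gain * trigger_level * duration / 1000.0
    aim = _rotate(aim0 - leak_drift_sacc * u_goal, draws.direction_jitter)
    amplitude = float(np.hypot(*aim))
    u_aim = aim / amplitude

    burst_start = profile_start - config.efference_delay
    t_end = max(profile_start + duration, blink + config.brem_duration) + 200.0
    time = np.arange(0.0, t_end, dt)

    bell, _, duration = saccade_profile(time, burst_start, amplitude, config.vmax, config.a0)
    burst = bell / config.burst_gain

    ramp = _build_blink_ramp(
        time, go, blink, draws.slope, mult, trigger_level / draws.q, burst_start + duration
    )
    eta = smooth_unit_noise(rng, len(time), config.rate_noise_smooth_ms / dt)
    prep = draws.q * ramp * (1.0 + config.rate_noise_sd * eta)
    motor = draws.burst_gain_jitter * burst * (1.0 + config.burst_noise_sd * eta)
    rate = np.clip(config.baseline_rate + prep + motor, 0.0, None)
    spikes = _poisson_spikes(rng, rate, time, dt)

    # --- velocity: BREM + leak (gate open) + saccadic burst ------------------
    vh = np.zeros_like(time)
    vv = np.zeros_like(time)
    i_blink = int(round(blink / dt))
    n_brem = min(len(brem.time), len(time) - i_blink)
    vh[i_blink : i_blink + n_brem] += brem.h_vel[:n_brem]
    vv[i_blink : i_blink + n_brem] += brem.v_vel[:n_brem]

    gate = (time >= blink) & (time <= profile_start + duration)
    leak = config.leak_gain * _shift_forward(prep, d_samples) * gate
    vh += leak * u_goal[0]
    vv += leak * u_goal[1]

    sacc_mag = config.burst_gain * _shift_forward(motor, d_samples)
    vh += sacc_mag * u_aim[0]
    vv += sacc_mag * u_aim[1]
    vh += _drift_velocity(config, rng, len(time))
    vv += _drift_velocity(config, rng, len(time))

    # --- ground truth --------------------------------------------------------
    _, tmpl_h, tmpl_v = brem_template_mean(config)
    gain = (brem.h_vel[np.argmax(np.abs(tmpl_h))] / tmpl_h[np.argmax(np.abs(tmpl_h))]) if np.any(tmpl_h) else 1.0
    clean_onset = _component_onset(tmpl_h * gain, tmpl_v * gain, brem.time)
    movement_onset = blink + (clean_onset if clean_onset is not None else 0.0)
    # saccade onset per the same criterion convention as control trials: the
    # detector's velocity criterion applied to the noise-free saccade
    clean_sacc = config.burst_gain * _shift_forward(draws.burst_gain_jitter * burst, d_samples)
    true_sacc_onset = _component_onset(clean_sacc * u_aim[0], clean_sacc * u_aim[1], time)
    if true_sacc_onset is None:
        true_sacc_onset = profile_start

    noise = config.position_noise_sd
    eye = EyeTrace(
        time=time,
        h_pos=_integrate(vh, dt_s) + noise * rng.standard_normal(len(time)),
        v_pos=_integrate(vv, dt_s) + noise * rng.standard_normal(len(time)),
    )
    trial = TrialRecord(
        trial_id=trial_id,
        condition=BLINK,
        target=(float(target[0]), float(target[1])),
        eye=eye,
        spikes=spikes,
        target_on=config.target_onset,
        go_cue=go,
        blink_on=blink,
    )
    truth = TrialTruth(
        trial_id=trial_id,
        condition=BLINK,
        rate_scale=draws.q,
        slope_pre=eff_slope,
        slope_post=mult * eff_slope,
        gate_open=blink,
        saccade_onset=true_sacc_onset,
        profile_start=profile_start,
        movement_onset=movement_onset,
        onset_delay=true_sacc_onset - movement_onset,
        reaction_time=profile_start - go,
    )
    return trial, truth


def generate_brem_trial(config: GeneratorConfig, rng: np.random.Generator, trial_id: int = 0) -> tuple[TrialRecord, TrialTruth]:
    """One fixation trial with an air-puff blink and no target: pure BREM."""
    dt = config.dt
    blink = 200.0
    t_end = blink + config.brem_duration + 150.0
    time = np.arange(0.0, t_end, dt)
    brem = generate_brem_velocity(config, rng)

    vh = np.zeros_like(time)
    vv = np.zeros_like(time)
    i_blink = int(round(blink / dt))
    n_brem = min(len(brem.time), len(time) - i_blink)
    vh[i_blink : i_blink + n_brem] = brem.h_vel[:n_brem]
    vv[i_blink : i_blink + n_brem] = brem.v_vel[:n_brem]

    vh += _drift_velocity(config, rng, len(time))
    vv += _drift_velocity(config, rng, len(time))

    rate = np.full_like(time, config.baseline_rate)
    spikes = _poisson_spikes(rng, rate, time, dt)
    dt_s = dt / 1000.0
    noise = config.position_noise_sd
    eye = EyeTrace(
        time=time,
        h_pos=_integrate(vh, dt_s) + noise * rng.standard_normal(len(time)),
        v_pos=_integrate(vv, dt_s) + noise * rng.standard_normal(len(time)),
    )
    trial = TrialRecord(
        trial_id=trial_id, condition=BREM, target=None, eye=eye, spikes=spikes, blink_on=blink
    )
    truth = TrialTruth(
        trial_id=trial_id,
        condition=BREM,
        rate_scale=1.0,
        slope_pre=0.0,
        slope_post=0.0,
        gate_open=blink,
    )
    return trial, truth


def generate_session(config: GeneratorConfig, session_id: str | None = None) -> Session:
    """A full session: BREM, control, and blink trials plus ground truth.

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if session_id is None:
        session_id = f"synthetic-{config.seed:06d}"

    trials: list[TrialRecord] = []
    truth = GroundTruth(
        efference_delay=config.efference_delay,
        threshold_rate=config.threshold_rate,
        blink_threshold_fraction=config.blink_threshold_fraction,
        post_blink_slope_multiplier=config.post_blink_slope_multiplier,
    )
    tid = 0
    for _ in range(config.n_brem_trials):
        tr, tt = generate_brem_trial(config, rng, tid)
        trials.append(tr)
        truth.trials[tid] = tt
        tid += 1
    for _ in range(config.n_control_trials):
        tr, tt = generate_control_trial(config, rng, tid)
        trials.append(tr)
        truth.trials[tid] = tt
        tid += 1
    for _ in range(config.n_blink_trials):
        tr, tt = generate_blink_trial(config, rng, tid)
        trials.append(tr)
        truth.trials[tid] = tt
        tid += 1
    return Session(session_id=session_id, trials=trials, ground_truth=truth)


def generate_population(config: GeneratorConfig, n_neurons: int, base_seed: int | None = None) -> list[Session]:
    """Independent single-neuron sessions with seeds derived from one base seed."""
    if n_neurons < 1:
        raise ConfigError("n_neurons", "must be >= 1")
    base = config.seed if base_seed is None else base_seed
    seeds = np.random.SeedSequence(base).generate_state(n_neurons) % (2**31 - 1)
    sessions = []
    for i, s in enumerate(seeds):
        cfg = GeneratorConfig.from_dict({**config.to_dict(), "seed": int(s)})
        sessions.append(generate_session(cfg, session_id=f"neuron-{i:03d}"))
    return sessions
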