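"""Velocity estimation, spike-density functions, movement detection, and
rate normalization.

Conventions: eye position is smoothed with a zero-phase Gaussian kernel
(s.d. ~2 ms at 1 kHz) and centrally differenced; spike densities use a Gaussian kernel whose *width* is its
standard deviation (3 ms for across-trial correlation and threshold
analyses, 10 ms for accumulation-rate estimation); movements are detected
with standard velocity criteria (50 deg/s onset, 30 deg/s offset) applied
independently to the horizontal and vertical components, taking the
earlier onset and the later offset.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .containers import EyeTrace, SaccadeEvent, SpikeDensity, TrialRecord

ONSET_CRITERION = 50.0  # deg/s
OFFSET_CRITERION = 30.0  # deg/s
DEFAULT_SMOOTH_SD_MS = 1.5


class TraceTooShortError(ValueError):
    """Position trace shorter than the smoothing filter warm-up."""


class NormalizationError(ValueError):
    """Peak trial-averaged control rate is zero; normalization undefined."""


def compute_velocity(trace: EyeTrace, smooth_sd_ms: float = DEFAULT_SMOOTH_SD_MS) -> EyeTrace:
    """Differentiate positions into velocities after zero-phase smoothing.

    Positions are smoothed with a symmetric Gaussian kernel (zero group
    delay, so velocity features are not shifted in time) and centrally
    differenced.  The kernel is compact in time (s.d. ~2 ms), which keeps
    acausal leakage of the steep saccadic edge into neighbouring samples
    minimal -- important when pre-onset velocities are analysed in their own
    right.  Returns a new EyeTrace with h_vel / v_vel filled in (deg/s).
    """
    sd_samples = smooth_sd_ms / trace.dt
    min_len = int(8 * sd_samples) + 3
    if len(trace.time) <= min_len:
        raise TraceTooShortError(
            f"trace has {len(trace.time)} samples; needs more than {min_len} for smoothing"
        )
    vels = []
    for pos in (trace.h_pos, trace.v_pos):
        smoothed = gaussian_filter1d(pos, sd_samples, mode="nearest")
        vels.append(np.gradient(smoothed, trace.time / 1000.0))
    return EyeTrace(
        time=trace.time,
        h_pos=trace.h_pos,
        v_pos=trace.v_pos,
        h_vel=vels[0],
        v_vel=vels[1],
    )


def spike_density(
    spike_times: np.ndarray,
    kernel_width: float,
    window: tuple[float, float],
    dt: float = 1.0,
) -> SpikeDensity:
    """Gaussian-kernel spike density on a ms grid within `window`.

    The kernel has s.d. `kernel_width` (ms) and unit area in seconds, so the
    density integrates to the spike count when the window covers all kernels.
    An empty train yields an all-zero density.
    """
    if kernel_width <= 0:
        raise ValueError("kernel_width must be > 0")
    t0, t1 = window
    time = np.arange(t0, t1 + 0.5 * dt, dt)
    spikes = np.asarray(spike_times, dtype=float)
    if len(spikes) == 0:
        return SpikeDensity(time=time, rate=np.zeros_like(time), kernel_width=kernel_width)
    # only spikes whose kernel reaches into the window contribute
    keep = (spikes > t0 - 8 * kernel_width) & (spikes < t1 + 8 * kernel_width)
    spikes = spikes[keep]
    diff = time[:, None] - spikes[None, :]
    norm = 1.0 / (kernel_width * np.sqrt(2.0 * np.pi))
    rate = 1000.0 * norm * np.exp(-0.5 * (diff / kernel_width) ** 2).sum(axis=1)
    return SpikeDensity(time=time, rate=rate, kernel_width=kernel_width)


def detect_movement(
    trace: EyeTrace,
    onset_criterion: float = ONSET_CRITERION,
    offset_criterion: float = OFFSET_CRITERION,
    search_start: float | None = None,
) -> Optional[SaccadeEvent]:
    """Velocity-criterion movement detection on a trace with velocities.

    Onset and offset are found independently per component (first sample with
    |v| >= onset criterion; first subsequent sample with |v| < offset
    criterion); the overall onset is the minimum of the component onsets and
    the overall offset the maximum of the component offsets.  Returns None
    when neither component crosses the onset criterion ("no movement"), never
    raises for that case.
    """
    if trace.h_vel is None or trace.v_vel is None:
        raise ValueError("trace has no velocities; run compute_velocity first")
    time = trace.time
    start_idx = 0 if search_start is None else int(np.searchsorted(time, search_start))
    onsets, offsets = [], []
    for v in (trace.h_vel, trace.v_vel):
        speed = np.abs(v)
        above = np.flatnonzero(speed[start_idx:] >= onset_criterion)
        if len(above) == 0:
            continue
        i_on = start_idx + above[0]
        below = np.flatnonzero(speed[i_on:] < offset_criterion)
        i_off = i_on + below[0] if len(below) else len(time) - 1
        onsets.append(time[i_on])
        offsets.append(time[i_off])
    if not onsets:
        return None
    onset = min(onsets)
    offset = max(offsets)
    comp_names = []
    for name, v in (("horizontal", trace.h_vel), ("vertical", trace.v_vel)):
        above = np.flatnonzero(np.abs(v[start_idx:]) >= onset_criterion)
        if len(above):
            comp_names.append((time[start_idx + above[0]], name))
    component = min(comp_names)[1]

    sel = (time >= onset) & (time <= offset)
    speed = np.hypot(trace.h_vel, trace.v_vel)
    peak = float(speed[sel].max()) if sel.any() else float("nan")
    i_on, i_off = int(np.searchsorted(time, onset)), int(np.searchsorted(time, offset))
    amplitude = float(
        np.hypot(trace.h_pos[i_off] - trace.h_pos[i_on], trace.v_pos[i_off] - trace.v_pos[i_on])
    )
    return SaccadeEvent(
        onset=float(onset),
        offset=float(offset),
        component_of_onset=component,
        peak_velocity=peak,
        amplitude=amplitude,
    )


def trial_densities(
    trials: Sequence[TrialRecord],
    kernel_width: float,
    dt: float = 1.0,
) -> list[SpikeDensity]:
    """Per-trial spike densities over each trial's own time grid."""
    out = []
    for tr in trials:
        t0, t1 = float(tr.eye.time[0]), float(tr.eye.time[-1])
        out.append(spike_density(tr.spikes, kernel_width, (t0, t1), dt))
    return out


def aligned_rate_matrix(
    densities: Sequence[SpikeDensity],
    align_times: Sequence[float],
    window: tuple[float, float],
    dt: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-trial densities on a grid aligned to per-trial event times.

    Returns (times relative to the event, matrix of shape trials x times).
    Samples outside a trial's support are NaN.
    """
    rel = np.arange(window[0], window[1] + 0.5 * dt, dt)
    mat = np.full((len(densities), len(rel)), np.nan)
    for i, (dens, t_align) in enumerate(zip(densities, align_times)):
        want = t_align + rel
        idx = np.round((want - dens.time[0]) / dt).astype(int)
        ok = (idx >= 0) & (idx < len(dens.time))
        mat[i, ok] = dens.rate[idx[ok]]
    return rel, mat


def aligned_signal_matrix(
    signals: Sequence[np.ndarray],
    signal_times: Sequence[np.ndarray],
    align_times: Sequence[float],
    window: tuple[float, float],
    dt: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Like aligned_rate_matrix for arbitrary per-trial signals."""
    rel = np.arange(window[0], window[1] + 0.5 * dt, dt)
    mat = np.full((len(signals), len(rel)), np.nan)
    for i, (sig, times, t_align) in enumerate(zip(signals, signal_times, align_times)):
        want = t_align + rel
        idx = np.round((want - times[0]) / dt).astype(int)
        ok = (idx >= 0) & (idx < len(sig))
        mat[i, ok] = sig[idx[ok]]
    return rel, mat


def control_peak_rate(
    control_densities: Sequence[SpikeDensity],
    align_times: Sequence[float],
    window: tuple[float, float] = (-100.0, 150.0),
    dt: float = 1.0,
) -> float:
    """Peak of the saccade-aligned, trial-averaged control density (spikes/s)."""
    if len(control_densities) == 0:
        raise NormalizationError("no control trials to derive the normalizer from")
    _, mat = aligned_rate_matrix(control_densities, align_times, window, dt)
    avg = np.nanmean(mat, axis=0)
    peak = float(np.nanmax(avg))
    if not np.isfinite(peak) or peak <= 0:
        raise NormalizationError("peak trial-averaged control rate is zero")
    return peak


def normalize_rates(matrices: Sequence[np.ndarray], divisor: float) -> list[np.ndarray]:
    """Divide every trial's density by the control-derived peak (shared divisor)."""
    if divisor <= 0:
        raise NormalizationError("normalization divisor must be > 0")
    return [m / divisor for m in matrices]
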