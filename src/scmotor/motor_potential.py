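"""Across-trial lagged correlation between activity and kinematics, the
optimal efferent delay, and trial-shuffled bootstrap significance.

For one neuron, the motor potential at movement time t and lag D is the
Pearson correlation, across trials, between the activity vector a(t + D) and
the kinematics vector v(t).  Maps are averaged across neurons; for each
movement time the activity time with the highest population correlation
gives the optimal efferent delay (negative = activity leads velocity,
causal).  Significance comes from shuffling trial identities between the
activity and velocity vectors and asking whether the 95% CI of the
actual-minus-shuffled difference excludes zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

MIN_TRIALS = 7
DEFAULT_LAGS = (-50, 50)
DEFAULT_N_SHUFFLES = 100
SMOOTH_WINDOW_MS = 5


@dataclass
class LaggedCorrelationMap:
    """Correlation over (movement time x lag) for one neuron or a population.

    `corr[i, j]` is the Pearson coefficient at movement time `movement_time[i]`
    and lag `lags[j]` (activity at t + lag vs kinematics at t).  Cells where
    either across-trial vector has zero variance are NaN and excluded from
    averages.
    """

    movement_time: np.ndarray  # ms relative to saccade onset
    lags: np.ndarray  # ms
    corr: np.ndarray  # (n_times, n_lags)
    n_trials: int

    def __post_init__(self) -> None:
        finite = self.corr[np.isfinite(self.corr)]
        if finite.size and (finite.min() < -1.000001 or finite.max() > 1.000001):
            raise ValueError("correlation values outside [-1, 1]")


@dataclass
class EfferentDelayTrace:
    """Optimal activity lead per movement time (5 ms moving-averaged)."""

    movement_time: np.ndarray
    optimal_delay: np.ndarray  # ms; negative = causal (activity leads)
    raw_delay: np.ndarray | None = None  # per-time argmax before smoothing
    smoothed: bool = True


@dataclass
class BootstrapNull:
    """Trial-shuffle null for the correlation time course at a fixed lag."""

    n_shuffles: int
    time: np.ndarray
    actual: np.ndarray
    shuffle_mean: np.ndarray
    ci_lower: np.ndarray  # 95% CI of the actual-minus-shuffled difference
    ci_upper: np.ndarray
    significant: np.ndarray  # bool per time point


class InsufficientTrialsError(ValueError):
    """Fewer trials than the minimum needed for across-trial correlation."""


def _zscore_columns(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise z-scores (population s.d.); returns (z, valid-column mask).

    Columns with any NaN or zero variance are invalid.
    """
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0)
    valid = np.isfinite(mean) & (sd > 0)
    z = np.zeros_like(mat)
    np.divide(mat - mean, sd, out=z, where=valid[None, :])
    return z, valid


def lagged_correlation_map(
    activity: np.ndarray,
    activity_times: np.ndarray,
    kinematics: np.ndarray,
    kinematics_times: np.ndarray,
    lags: tuple[int, int] = DEFAULT_LAGS,
    dt: float = 1.0,
) -> LaggedCorrelationMap:
    """Per-neuron correlation map c(t + D, t) across trials.

    `activity` (trials x activity-time grid) must cover the kinematics window
    extended by the lag range.  Both matrices are aligned to saccade onset on
    the same ms grid.  Raises InsufficientTrialsError below 7 trials (callers
    exclude such neurons rather than crash).
    """
    if activity.shape[0] != kinematics.shape[0]:
        raise ValueError("activity and kinematics must have the same trial count")
    n_trials = activity.shape[0]
    if n_trials < MIN_TRIALS:
        raise InsufficientTrialsError(f"{n_trials} trials < minimum {MIN_TRIALS}")

    lag_grid = np.arange(lags[0], lags[1] + 1, int(dt))
    za, valid_a = _zscore_columns(activity)
    zv, valid_v = _zscore_columns(kinematics)

    n_t = kinematics.shape[1]
    corr = np.full((n_t, len(lag_grid)), np.nan)
    a0 = activity_times[0]
    for j, lag in enumerate(lag_grid):
        want = kinematics_times + lag
        idx = np.round((want - a0) / dt).astype(int)
        ok = (idx >= 0) & (idx < activity.shape[1])
        cols = idx[ok]
        cell_valid = valid_a[cols] & valid_v[ok]
        vals = (za[:, cols] * zv[:, ok]).mean(axis=0)
        vals[~cell_valid] = np.nan
        corr[ok, j] = vals

    # pairwise-complete fallback: kinematics columns with missing trials
    # (e.g. samples before a blink movement existed) use the trial subset
    # with data, provided at least MIN_TRIALS trials remain
    partial = np.flatnonzero(~valid_v & (np.sum(np.isfinite(kinematics), axis=0) >= MIN_TRIALS))
    for t_idx in partial:
        rows = np.isfinite(kinematics[:, t_idx])
        v = kinematics[rows, t_idx]
        if v.std() == 0:
            continue
        zvp = (v - v.mean()) / v.std()
        a_sub = activity[rows]
        mean = a_sub.mean(axis=0)
        sd = a_sub.std(axis=0)
        col_ok = np.isfinite(mean) & (sd > 0)
        zap = np.zeros_like(a_sub)
        np.divide(a_sub - mean, sd, out=zap, where=col_ok[None, :])
        idx = np.round((kinematics_times[t_idx] + lag_grid - a0) / dt).astype(int)
        ok = (idx >= 0) & (idx < activity.shape[1])
        vals = (zap[:, idx[ok]] * zvp[:, None]).mean(axis=0)
        vals[~col_ok[idx[ok]]] = np.nan
        corr[t_idx, ok] = vals
    return LaggedCorrelationMap(
        movement_time=np.asarray(kinematics_times, dtype=float),
        lags=lag_grid.astype(float),
        corr=corr,
        n_trials=n_trials,
    )


def population_average_map(maps: Sequence[LaggedCorrelationMap]) -> LaggedCorrelationMap:
    """Unweighted mean over neurons per cell, ignoring missing cells."""
    if len(maps) == 0:
        raise ValueError("need at least one neuron map")
    ref = maps[0]
    for m in maps[1:]:
        if m.corr.shape != ref.corr.shape:
            raise ValueError("neuron maps must share the (time x lag) grid")
    stack = np.stack([m.corr for m in maps])
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(stack, axis=0)
    return LaggedCorrelationMap(
        movement_time=ref.movement_time,
        lags=ref.lags,
        corr=avg,
        n_trials=int(np.mean([m.n_trials for m in maps])),
    )


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks at the edges; NaNs skipped."""
    half = window // 2
    out = np.full_like(x, np.nan)
    for i in range(len(x)):
        seg = x[max(0, i - half) : i + half + 1]
        seg = seg[np.isfinite(seg)]
        if len(seg):
            out[i] = seg.mean()
    return out


def optimal_delay_trace(
    pop_map: LaggedCorrelationMap,
    smooth_window_ms: int = SMOOTH_WINDOW_MS,
) -> EfferentDelayTrace:
    """Per movement time, the lag of the population-correlation peak along the
    activity axis, then a 5 ms moving average.

    Ties are broken toward the most negative (most causal) lag; all-missing
    columns yield NaN at that time.
    """
    delays = np.full(len(pop_map.movement_time), np.nan)
    for i, row in enumerate(pop_map.corr):
        if np.all(np.isnan(row)):
            continue
        # lags ascend, argmax returns the first (most causal) maximum
        delays[i] = pop_map.lags[np.nanargmax(row)]
    dt = float(pop_map.movement_time[1] - pop_map.movement_time[0]) if len(pop_map.movement_time) > 1 else 1.0
    window = max(1, int(round(smooth_window_ms / dt)))
    return EfferentDelayTrace(
        movement_time=pop_map.movement_time,
        optimal_delay=_moving_average(delays, window),
        raw_delay=delays,
        smoothed=True,
    )


def mean_efferent_delay(
    trace: EfferentDelayTrace,
    window: tuple[float, float],
    min_points: int = 5,
) -> float:
    """Arithmetic mean of the optimal delay over a movement-time window (ms)."""
    sel = (trace.movement_time >= window[0]) & (trace.movement_time <= window[1])
    vals = trace.optimal_delay[sel]
    vals = vals[np.isfinite(vals)]
    if len(vals) < min_points:
        raise ValueError(
            f"only {len(vals)} defined delay points in window {window}; need >= {min_points}"
        )
    return float(vals.mean())


def correlation_timecourse_at_delay(
    pop_map: LaggedCorrelationMap,
    delay: float,
) -> np.ndarray:
    """Slice of the population map at the grid lag nearest `delay`."""
    if not (pop_map.lags[0] <= delay <= pop_map.lags[-1]):
        raise ValueError(f"delay {delay} outside the lag grid")
    j = int(np.argmin(np.abs(pop_map.lags - delay)))
    if pop_map.lags[j] != delay:
        log.info("delay %.2f ms rounded to nearest grid lag %.0f ms", delay, pop_map.lags[j])
    return pop_map.corr[:, j].copy()


def _population_trace_at_lag(
    neuron_data: Sequence[tuple[np.ndarray, np.ndarray]],
    activity_offset: int,
    lag: int,
    n_times: int,
) -> np.ndarray:
    """Population-average correlation time course at one lag.

    `neuron_data` holds per-neuron (activity, kinematics) matrices; activity
    column `activity_offset + t + lag` pairs with kinematics column `t`.
    """
    traces = np.full((len(neuron_data), n_times), np.nan)
    for i, (act, kin) in enumerate(neuron_data):
        za, valid_a = _zscore_columns(act)
        zv, valid_v = _zscore_columns(kin)
        cols = np.arange(n_times) + activity_offset + lag
        ok = (cols >= 0) & (cols < act.shape[1])
        vals = (za[:, cols[ok]] * zv[:, ok]).mean(axis=0)
        vals[~(valid_a[cols[ok]] & valid_v[ok])] = np.nan
        traces[i, ok] = vals
        # pairwise-complete fallback for partially missing kinematics columns
        partial = np.flatnonzero(
            ok & ~valid_v & (np.sum(np.isfinite(kin), axis=0) >= MIN_TRIALS)
        )
        for t_idx in partial:
            rows = np.isfinite(kin[:, t_idx])
            v = kin[rows, t_idx]
            a = act[rows, cols[t_idx]]
            if v.std() == 0 or a.std() == 0 or not np.all(np.isfinite(a)):
                continue
            traces[i, t_idx] = float(
                ((a - a.mean()) / a.std() * (v - v.mean()) / v.std()).mean()
            )
    with np.errstate(invalid="ignore"):
        return np.nanmean(traces, axis=0)


def bootstrap_significance(
    neuron_data: Sequence[tuple[np.ndarray, np.ndarray]],
    movement_time: np.ndarray,
    activity_times: np.ndarray,
    delay: float,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
) -> BootstrapNull:
    """Trial-shuffle bootstrap for the correlation time course at one lag.

    Per shuffle, trial identities are permuted between the across-trial
    activity and velocity vectors of every neuron and the population-average
    correlation is recomputed.  A time point is significant when the lower
    bound of the (actual - shuffled) difference distribution exceeds 0, i.e.
    the test is one-sided for excess *positive* correlation.  The motor
    potential hypothesis is directional -- activity is supposed to drive
    velocity with a positive gain -- and a one-sided test also ignores the
    small negative coupling that velocity-threshold alignment induces just
    before movement onset (trials with steeper bursts mechanically have lower
    velocity a few ms before the threshold crossing).
    """
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles")
    rng = np.random.default_rng(seed)
    dt = float(movement_time[1] - movement_time[0]) if len(movement_time) > 1 else 1.0
    lag = int(round(delay / dt))
    offset = int(round((movement_time[0] - activity_times[0]) / dt))
    n_times = len(movement_time)

    actual = _population_trace_at_lag(neuron_data, offset, lag, n_times)
    shuffled = np.full((n_shuffles, n_times), np.nan)
    for k in range(n_shuffles):
        permuted = [
            (act, kin[rng.permutation(kin.shape[0])]) for act, kin in neuron_data
        ]
        shuffled[k] = _population_trace_at_lag(permuted, offset, lag, n_times)

    diffs = actual[None, :] - shuffled
    # Conservative order-statistic estimate of the 2.5 / 97.5 percentiles:
    # with a finite number of shuffles, interpolated percentiles understate
    # the interval and make the pointwise test anti-conservative, so the
    # bound is taken one order statistic further out.
    k = max(0, int(np.floor(0.025 * n_shuffles)) - 1)
    sorted_diffs = np.sort(diffs, axis=0)
    ci_lower = sorted_diffs[k]
    ci_upper = sorted_diffs[n_shuffles - 1 - k]
    significant = np.where(
        np.isfinite(ci_lower) & np.isfinite(ci_upper) & np.isfinite(actual),
        ci_lower > 0,
        False,
    )
    with np.errstate(invalid="ignore"):
        shuffle_mean = np.nanmean(shuffled, axis=0)
    return BootstrapNull(
        n_shuffles=n_shuffles,
        time=np.asarray(movement_time, dtype=float),
        actual=actual,
        shuffle_mean=shuffle_mean,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        significant=significant.astype(bool),
    )
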