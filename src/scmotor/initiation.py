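"""Initiation-criterion (threshold) analysis and accumulation-rate-change
analysis with pseudo-blink surrogate controls.

The threshold analysis compares normalized, saccade-aligned activity between
blink and control trials in 10 ms bins slid from 50 ms before to 20 ms after
saccade onset: paired Wilcoxon signed-rank across neurons per bin, a linear
fit to the blink-vs-control scatter, and a per-neuron higher/lower/no-diff
classification (rank-sum across trials at alpha = 0.001).

The accumulation-rate analysis fits two independent least-squares lines to
the trial-averaged 10 ms-kernel density in the 20 ms before and after blink
onset; the slope change is summarized by the rate modulation index
(post - pre) / (post + pre) and compared against a surrogate built from
control trials with pseudo-blink times resampled from the session's
empirical blink-time distribution (1000 pseudo-trials by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

THRESHOLD_BINS = [(-50 + 10 * i, -40 + 10 * i) for i in range(7)]  # ms re saccade onset
CLASS_ALPHA = 0.001
TEST_ALPHA = 0.05
MIN_NEURONS_FOR_TEST = 6
MIN_TRIALS_FOR_CLASS = 3
DEFAULT_N_PSEUDO = 1000
RATE_FIT_HALF_WINDOW = 20.0  # ms each side of the blink


@dataclass
class BinComparison:
    """One 10 ms bin's population comparison."""

    window: tuple[float, float]
    p_value: float
    control_higher: bool
    fit_slope: float  # blink regressed on control
    fit_intercept: float
    n_pairs: int


@dataclass
class ThresholdComparison:
    bins: list[BinComparison]
    control_means: np.ndarray  # (neurons x bins) mean normalized rate
    blink_means: np.ndarray
    classes: np.ndarray  # (neurons x bins) of {"higher", "lower", "nodiff"}
    proportions: dict[str, np.ndarray]  # class -> per-bin fraction of neurons


@dataclass
class RateFitResult:
    """Pre/post-blink accumulation slopes (normalized rate per ms)."""

    rate_pre: float
    rate_post: float
    condition: str  # "blink" | "control-surrogate"

    @property
    def modulation_index(self) -> Optional[float]:
        return rate_modulation_index(self.rate_pre, self.rate_post)


@dataclass
class SurrogateDataset:
    """Control trials re-labelled with pseudo-blink times resampled from the
    session's empirical blink-time distribution."""

    trial_indices: np.ndarray  # indices into the session's control trials
    pseudo_blink_times: np.ndarray  # ms, one per pseudo-trial
    seed: int


# ---------------------------------------------------------------------------
# threshold analysis
# ---------------------------------------------------------------------------

def binned_activity(
    rel_time: np.ndarray,
    rate_matrix: np.ndarray,
    bins: Sequence[tuple[float, float]] = tuple(THRESHOLD_BINS),
) -> np.ndarray:
    """Trial-averaged normalized rate within each bin.

    `rate_matrix` is (trials x times) aligned to saccade onset and already
    normalized by the control-derived divisor.  Bins with no support are NaN.
    Bin windows are half-open [lo, hi) so consecutive 10 ms bins tile without
    double counting.
    """
    out = np.full(len(bins), np.nan)
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(rate_matrix, axis=0)
    for i, (lo, hi) in enumerate(bins):
        sel = (rel_time >= lo) & (rel_time < hi)
        if sel.any() and np.isfinite(avg[sel]).any():
            out[i] = np.nanmean(avg[sel])
    return out


def per_trial_binned_activity(
    rel_time: np.ndarray,
    rate_matrix: np.ndarray,
    bins: Sequence[tuple[float, float]] = tuple(THRESHOLD_BINS),
) -> np.ndarray:
    """Per-trial mean normalized rate per bin, shape (trials x bins)."""
    out = np.full((rate_matrix.shape[0], len(bins)), np.nan)
    for i, (lo, hi) in enumerate(bins):
        sel = (rel_time >= lo) & (rel_time < hi)
        if sel.any():
            with np.errstate(invalid="ignore"):
                out[:, i] = np.nanmean(rate_matrix[:, sel], axis=1)
    return out


def population_bin_comparison(
    control_means: np.ndarray,
    blink_means: np.ndarray,
    bins: Sequence[tuple[float, float]] = tuple(THRESHOLD_BINS),
    alpha: float = TEST_ALPHA,
) -> list[BinComparison]:
    """Per-bin paired signed-rank test + least-squares blink-vs-control fit.

    Inputs are (neurons x bins) matrices of per-neuron mean normalized rates.
    Ties / zero differences follow the standard signed-rank zero-exclusion.
    With fewer than 6 complete pairs the test is skipped with a warning
    (p = NaN).
    """
    results = []
    for i, window in enumerate(bins):
        c = control_means[:, i]
        b = blink_means[:, i]
        ok = np.isfinite(c) & np.isfinite(b)
        c, b = c[ok], b[ok]
        n = int(ok.sum())
        if n < MIN_NEURONS_FOR_TEST:
            log.warning("bin %s: only %d neuron pairs; test skipped", window, n)
            results.append(BinComparison(window, float("nan"), False, float("nan"), float("nan"), n))
            continue
        diff = c - b
        if np.allclose(diff, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(c, b, zero_method="wilcox").pvalue)
        slope, intercept = np.polyfit(c, b, 1)
        results.append(
            BinComparison(
                window=window,
                p_value=p,
                control_higher=bool(p < alpha and np.median(diff) > 0),
                fit_slope=float(slope),
                fit_intercept=float(intercept),
                n_pairs=n,
            )
        )
    return results


def classify_neuron_timecourse(
    control_trial_bins: Sequence[np.ndarray],
    blink_trial_bins: Sequence[np.ndarray],
    bins: Sequence[tuple[float, float]] = tuple(THRESHOLD_BINS),
    alpha: float = CLASS_ALPHA,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Per-neuron higher/lower/no-diff class per bin, plus population proportions.

    Inputs are per-neuron (trials x bins) matrices of per-trial binned rates.
    The class is decided by a two-sided Wilcoxon rank-sum test across trials
    at alpha = 0.001; fewer than 3 trials in either condition yields "nodiff"
    with an insufficient-data log entry.  The three per-bin proportions sum
    to 1.

    As class *traces* the windows are labeled by their right edge: the class
    reported at time t summarizes activity over [t - 10, t), i.e. only
    activity strictly before t, so a pre-onset label never mixes in the
    shared saccadic transient at or after the labeled time.
    """
    n_neurons = len(control_trial_bins)
    classes = np.full((n_neurons, len(bins)), "nodiff", dtype=object)
    for ni, (ctrl, blnk) in enumerate(zip(control_trial_bins, blink_trial_bins)):
        for bi in range(len(bins)):
            c = ctrl[:, bi]
            b = blnk[:, bi]
            c = c[np.isfinite(c)]
            b = b[np.isfinite(b)]
            if len(c) < MIN_TRIALS_FOR_CLASS or len(b) < MIN_TRIALS_FOR_CLASS:
                log.info("neuron %d bin %s: insufficient trials for classification", ni, bins[bi])
                continue
            if np.ptp(np.concatenate([c, b])) == 0:
                continue
            p = float(stats.mannwhitneyu(b, c, alternative="two-sided").pvalue)
            if p < alpha:
                classes[ni, bi] = "higher" if np.median(b) > np.median(c) else "lower"
    proportions = {
        label: (classes == label).mean(axis=0) for label in ("higher", "lower", "nodiff")
    }
    return classes, proportions


# ---------------------------------------------------------------------------
# accumulation-rate analysis
# ---------------------------------------------------------------------------

def make_surrogate_control(
    n_control_trials: int,
    blink_times: Sequence[float],
    n_pseudo: int = DEFAULT_N_PSEUDO,
    seed: int = 0,
) -> SurrogateDataset:
    """Pseudo-trials: resampled control trials with pseudo-blink times drawn
    from the session's empirical blink-time distribution.  Deterministic
    given `seed`."""
    if n_control_trials < 1:
        raise ValueError("need at least one control trial")
    blink_times = np.asarray(blink_times, dtype=float)
    if blink_times.size == 0:
        raise ValueError("no blink trials in session; cannot build a surrogate")
    rng = np.random.default_rng(seed)
    return SurrogateDataset(
        trial_indices=rng.integers(0, n_control_trials, size=n_pseudo),
        pseudo_blink_times=rng.choice(blink_times, size=n_pseudo, replace=True),
        seed=seed,
    )


def piecewise_rate_fit(
    rel_time: np.ndarray,
    avg_density: np.ndarray,
    condition: str,
    half_window: float = RATE_FIT_HALF_WINDOW,
) -> RateFitResult:
    """Two independent least-squares lines on the 20 ms before / after the blink.

    `avg_density` is the trial-averaged, normalized, 10 ms-kernel density on a
    grid aligned to the (pseudo-)blink (time 0).  Slopes are in normalized
    rate per ms.
    """
    pre_sel = (rel_time >= -half_window) & (rel_time < 0)
    post_sel = (rel_time >= 0) & (rel_time <= half_window)
    slopes = []
    for sel in (pre_sel, post_sel):
        t = rel_time[sel]
        y = avg_density[sel]
        ok = np.isfinite(y)
        if ok.sum() < 5:
            raise ValueError("fewer than 5 samples on one side of the blink; cannot fit")
        slopes.append(float(np.polyfit(t[ok], y[ok], 1)[0]))
    return RateFitResult(rate_pre=slopes[0], rate_post=slopes[1], condition=condition)


def rate_modulation_index(rate_pre: float, rate_post: float) -> Optional[float]:
    """(post - pre) / (post + pre); None (excluded, flagged) when post + pre = 0."""
    denom = rate_post + rate_pre
    if denom == 0:
        log.warning("rate modulation index undefined (post + pre = 0); excluded")
        return None
    return (rate_post - rate_pre) / denom


@dataclass
class RateConditionComparison:
    p_pre: float
    p_post: float
    p_index: float
    blink_index_median: float
    surrogate_index_median: float
    blink_higher: bool
    n_neurons: int
    notes: list[str] = field(default_factory=list)


def compare_rate_conditions(
    blink_fits: Sequence[RateFitResult],
    surrogate_fits: Sequence[RateFitResult],
    alpha: float = TEST_ALPHA,
) -> RateConditionComparison:
    """Paired signed-rank tests on pre-rates, post-rates, and modulation indices.

    Fit lists are paired per neuron.  Neurons whose modulation index is
    undefined in either condition are dropped from the index test.
    """
    if len(blink_fits) != len(surrogate_fits):
        raise ValueError("fit lists must be paired per neuron")
    n = len(blink_fits)
    notes: list[str] = []
    if n < MIN_NEURONS_FOR_TEST:
        log.warning("only %d neurons; rate-condition tests skipped", n)
        return RateConditionComparison(
            float("nan"), float("nan"), float("nan"), float("nan"), float("nan"), False, n,
            notes=["skipped: fewer than 6 neurons"],
        )

    def paired_p(a: np.ndarray, b: np.ndarray) -> float:
        if np.allclose(a, b):
            return 1.0
        return float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)

    pre_b = np.array([f.rate_pre for f in blink_fits])
    pre_s = np.array([f.rate_pre for f in surrogate_fits])
    post_b = np.array([f.rate_post for f in blink_fits])
    post_s = np.array([f.rate_post for f in surrogate_fits])

    idx_pairs = [
        (bf.modulation_index, sf.modulation_index)
        for bf, sf in zip(blink_fits, surrogate_fits)
        if bf.modulation_index is not None and sf.modulation_index is not None
    ]
    if len(idx_pairs) < len(blink_fits):
        notes.append(f"{len(blink_fits) - len(idx_pairs)} neurons had undefined indices")
    idx_b = np.array([p[0] for p in idx_pairs])
    idx_s = np.array([p[1] for p in idx_pairs])

    p_index = paired_p(idx_b, idx_s) if len(idx_pairs) >= MIN_NEURONS_FOR_TEST else float("nan")
    return RateConditionComparison(
        p_pre=paired_p(pre_b, pre_s),
        p_post=paired_p(post_b, post_s),
        p_index=p_index,
        blink_index_median=float(np.median(idx_b)) if len(idx_b) else float("nan"),
        surrogate_index_median=float(np.median(idx_s)) if len(idx_s) else float("nan"),
        blink_higher=bool(
            len(idx_b) and p_index < alpha and np.median(idx_b - idx_s) > 0
        ),
        n_neurons=n,
        notes=notes,
    )
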