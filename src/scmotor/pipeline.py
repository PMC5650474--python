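"""Population-level analyses and the end-to-end reproducible run.

Each session contributes one neuron.  The population motor-potential map is
the unweighted mean of per-neuron lagged correlation maps; the efferent
delay is read off the per-time argmax of that map; the threshold and
accumulation-rate analyses compare conditions across the neuron population
with non-parametric paired tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as time_mod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import initiation as init
from . import motor_potential as mp
from . import session_processing as sp
from .config import GeneratorConfig
from .containers import Session
from .kinematics import endpoint_accuracy
from .session_processing import ProcessedSession
from .synth import generate_population

log = logging.getLogger(__name__)

DEFAULT_MOVEMENT_WINDOW = (-50.0, 50.0)
DEFAULT_POST_WINDOW = (0.0, 40.0)
DEFAULT_PRE_WINDOW = (-30.0, 0.0)


@dataclass
class RunConfig:
    """Configuration for a full generation + analysis run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_neurons: int = 20
    seed: int = 1
    movement_window: tuple[float, float] = DEFAULT_MOVEMENT_WINDOW
    lag_range: tuple[int, int] = mp.DEFAULT_LAGS
    post_window: tuple[float, float] = DEFAULT_POST_WINDOW
    pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW
    n_shuffles: int = mp.DEFAULT_N_SHUFFLES
    n_pseudo: int = init.DEFAULT_N_PSEUDO
    variant: str = "projected"  # "projected" | "raw" kinematics
    fisher_z: bool = False  # average Fisher-z transformed coefficients
    out_dir: Optional[str] = None
    input_dirs: Optional[list[str]] = None  # analyze existing bundles instead


@dataclass
class MotorPotentialResult:
    condition: str
    pop_map: mp.LaggedCorrelationMap
    delay_trace: mp.EfferentDelayTrace
    mean_delay_post: float
    mean_delay_pre: Optional[float]
    bootstrap: mp.BootstrapNull
    n_neurons: int
    significance_onset: Optional[float]  # earliest significant movement time


def _neuron_matrices(
    proc: ProcessedSession,
    condition: str,
    movement_window: tuple[float, float],
    lag_range: tuple[int, int],
) -> Optional[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Aligned (activity, kinematics) matrices for one neuron, or None if the
    neuron fails its inclusion criterion."""
    act_window = (movement_window[0] + lag_range[0], movement_window[1] + lag_range[1])
    if condition == "control":
        trials = [t for t in proc.control if t.saccade_onset is not None]
    else:
        if proc.inclusion is None or not proc.inclusion.in_motor_potential_set:
            return None
        trials = proc.triggered_blink
    if len(trials) < mp.MIN_TRIALS:
        return None
    at, act = sp.activity_matrix(proc, trials, act_window, kernel="corr")
    kt, kinm = sp.kinematics_matrix(proc, trials, movement_window)
    return at, act, kt, kinm


def population_motor_potential(
    processed: Sequence[ProcessedSession],
    condition: str,
    movement_window: tuple[float, float] = DEFAULT_MOVEMENT_WINDOW,
    lag_range: tuple[int, int] = mp.DEFAULT_LAGS,
    post_window: tuple[float, float] = DEFAULT_POST_WINDOW,
    pre_window: Optional[tuple[float, float]] = None,
    n_shuffles: int = mp.DEFAULT_N_SHUFFLES,
    seed: int = 0,
    fisher_z: bool = False,
) -> MotorPotentialResult:
    """Lagged-correlation motor potential across a neuron population.

    `condition` is "control" (saccade-aligned raw/projected kinematics) or
    "blink" (embedded-saccade-aligned projected residual kinematics on
    triggered trials).  The mean delay is evaluated over `post_window`
    (movement) and optionally `pre_window` (pre-onset, blink condition).
    """
    maps = []
    neuron_data = []
    at = kt = None
    for proc in processed:
        mats = _neuron_matrices(proc, condition, movement_window, lag_range)
        if mats is None:
            continue
        at, act, kt, kinm = mats
        nmap = mp.lagged_correlation_map(act, at, kinm, kt, lags=lag_range, dt=proc.dt)
        if fisher_z:
            nmap.corr[:] = np.arctanh(np.clip(nmap.corr, -0.999999, 0.999999))
        maps.append(nmap)
        neuron_data.append((act, kinm))
    if not maps:
        raise ValueError(f"no neurons pass the inclusion criteria for {condition!r}")

    pop = mp.population_average_map(maps)
    if fisher_z:
        pop.corr[:] = np.tanh(pop.corr)
    trace = mp.optimal_delay_trace(pop)
    mean_post = mp.mean_efferent_delay(trace, post_window)
    mean_pre = mp.mean_efferent_delay(trace, pre_window) if pre_window is not None else None

    boot = mp.bootstrap_significance(
        neuron_data,
        movement_time=pop.movement_time,
        activity_times=at,
        delay=float(np.round(mean_post)),
        n_shuffles=n_shuffles,
        seed=seed,
    )
    sig_times = pop.movement_time[boot.significant]
    return MotorPotentialResult(
        condition=condition,
        pop_map=pop,
        delay_trace=trace,
        mean_delay_post=mean_post,
        mean_delay_pre=mean_pre,
        bootstrap=boot,
        n_neurons=len(maps),
        significance_onset=float(sig_times[0]) if len(sig_times) else None,
    )


def _effective_n(x: np.ndarray) -> float:
    """Effective sample size of an autocorrelated series.

    Neighbouring per-millisecond argmax delays share trials and smooth rate
    noise, so they are strongly dependent (lag-1 autocorrelation up to ~0.9
    post-onset).  The usual correction n_eff = n / (1 + 2 sum(rho_k)) is
    applied with the sum truncated at the first non-positive autocorrelation.
    """
    x = x - x.mean()
    n = len(x)
    if n < 3 or np.allclose(x, 0):
        return float(n)
    denom = float(np.dot(x, x))
    s = 0.0
    for k in range(1, n - 1):
        rho = float(np.dot(x[:-k], x[k:])) / denom
        if rho <= 0:
            break
        s += rho
    return max(2.0, n / (1.0 + 2.0 * s))


def pre_post_delay_comparison(
    trace: mp.EfferentDelayTrace,
    pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW,
    post_window: tuple[float, float] = DEFAULT_POST_WINDOW,
) -> dict:
    """Welch t-test of the per-time optimal delays pre vs post onset.

    The test uses the unsmoothed per-time argmax delays (the 5 ms moving
    average used for display artificially shrinks the apparent variance of
    neighbouring points) and replaces the sample sizes with effective sizes
    that account for the strong serial dependence of neighbouring delays."""
    t = trace.movement_time
    d = trace.raw_delay if trace.raw_delay is not None else trace.optimal_delay
    pre = d[(t >= pre_window[0]) & (t <= pre_window[1])]
    post = d[(t > post_window[0]) & (t <= post_window[1])]
    pre, post = pre[np.isfinite(pre)], post[np.isfinite(post)]
    n1, n2 = _effective_n(pre), _effective_n(post)
    v1, v2 = pre.var(ddof=1), post.var(ddof=1)
    se = np.sqrt(v1 / n1 + v2 / n2)
    if se == 0:
        t_stat, p = 0.0, 1.0
    else:
        t_stat = (pre.mean() - post.mean()) / se
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    return {
        "pre_mean": float(pre.mean()),
        "post_mean": float(post.mean()),
        "t": float(t_stat),
        "p": float(p),
        "n_eff_pre": float(n1),
        "n_eff_post": float(n2),
    }


# ---------------------------------------------------------------------------
# threshold analysis
# ---------------------------------------------------------------------------

def threshold_analysis(
    processed: Sequence[ProcessedSession],
    bins: Sequence[tuple[float, float]] = tuple(init.THRESHOLD_BINS),
) -> init.ThresholdComparison:
    """Saccade-aligned binned-activity comparison for the threshold question.

    Uses every neuron with >= 7 detected blink trials; blink trials are
    aligned on the embedded saccade onset, control trials on the detected
    saccade onset; all rates share the control-derived normalizer.
    """
    window = (bins[0][0] - 5.0, bins[-1][1] + 5.0)
    control_means, blink_means = [], []
    control_trial_bins, blink_trial_bins = [], []
    for proc in processed:
        if proc.inclusion is None or not proc.inclusion.in_threshold_set:
            continue
        ctrl = [t for t in proc.control if t.saccade_onset is not None]
        blnk = proc.detected_blink
        rel_c, mat_c = sp.activity_matrix(proc, ctrl, window, kernel="corr")
        rel_b, mat_b = sp.activity_matrix(proc, blnk, window, kernel="corr")
        control_means.append(init.binned_activity(rel_c, mat_c, bins))
        blink_means.append(init.binned_activity(rel_b, mat_b, bins))
        control_trial_bins.append(init.per_trial_binned_activity(rel_c, mat_c, bins))
        blink_trial_bins.append(init.per_trial_binned_activity(rel_b, mat_b, bins))
    if not control_means:
        raise ValueError("no neurons pass the threshold-analysis inclusion criterion")
    control_means = np.stack(control_means)
    blink_means = np.stack(blink_means)
    comparisons = init.population_bin_comparison(control_means, blink_means, bins)
    classes, proportions = init.classify_neuron_timecourse(
        control_trial_bins, blink_trial_bins, bins
    )
    return init.ThresholdComparison(
        bins=comparisons,
        control_means=control_means,
        blink_means=blink_means,
        classes=classes,
        proportions=proportions,
    )


# ---------------------------------------------------------------------------
# accumulation-rate analysis
# ---------------------------------------------------------------------------

def accumulation_analysis(
    processed: Sequence[ProcessedSession],
    n_pseudo: int = init.DEFAULT_N_PSEUDO,
    seed: int = 0,
    window: tuple[float, float] = (-30.0, 30.0),
) -> dict:
    """Pre/post-blink accumulation slopes, blink vs pseudo-blink surrogate.

    Blink fits use the triggered (onset delay >= 20 ms) trials aligned on the
    actual blink; surrogate fits pool `n_pseudo` resampled control trials
    aligned on pseudo-blink times drawn from the session's empirical blink
    times.
    """
    blink_fits, surrogate_fits = [], []
    for i, proc in enumerate(processed):
        if proc.inclusion is None or not proc.inclusion.in_motor_potential_set:
            continue
        trig = proc.triggered_blink
        rel_b, mat_b = sp.blink_aligned_rate_matrix(proc, trig, window)
        with np.errstate(invalid="ignore"):
            avg_b = np.nanmean(mat_b, axis=0)
        blink_fits.append(init.piecewise_rate_fit(rel_b, avg_b, "blink"))

        ctrl = [t for t in proc.control if t.saccade_onset is not None]
        blink_times = [t.trial.blink_on for t in proc.blink]
        surr = init.make_surrogate_control(len(ctrl), blink_times, n_pseudo, seed=seed + i)
        dens = [proc.densities_rate[ctrl[j].trial.trial_id] for j in surr.trial_indices]
        from .preprocess import aligned_rate_matrix

        rel_s, mat_s = aligned_rate_matrix(dens, surr.pseudo_blink_times, window, proc.dt)
        with np.errstate(invalid="ignore"):
            avg_s = np.nanmean(mat_s, axis=0) / proc.norm_divisor_rate
        surrogate_fits.append(init.piecewise_rate_fit(rel_s, avg_s, "control-surrogate"))

    comparison = init.compare_rate_conditions(blink_fits, surrogate_fits)
    return {
        "blink_fits": blink_fits,
        "surrogate_fits": surrogate_fits,
        "comparison": comparison,
    }


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def behavioral_summary(processed: Sequence[ProcessedSession]) -> dict:
    """Reaction-time and endpoint-accuracy comparison, control vs blink.

    RT is measured from the GO cue to (embedded) saccade onset.  The RT test
    is one-tailed (blink < control); the accuracy test two-tailed; blink-time
    vs accuracy association uses Spearman correlation.
    """
    rt_control, rt_blink = [], []
    acc_control, acc_blink, blink_times = [], [], []
    for proc in processed:
        for t in proc.control:
            if t.saccade_onset is not None and t.trial.go_cue is not None:
                rt_control.append(t.saccade_onset - t.trial.go_cue)
                if t.endpoint is not None and t.trial.target is not None:
                    acc_control.append(endpoint_accuracy(t.endpoint, t.trial.target))
        for t in proc.detected_blink:
            if t.saccade_onset is not None and t.trial.go_cue is not None:
                rt_blink.append(t.saccade_onset - t.trial.go_cue)
                if t.endpoint is not None and t.trial.target is not None:
                    acc_blink.append(endpoint_accuracy(t.endpoint, t.trial.target))
                    blink_times.append(t.trial.blink_on - t.trial.go_cue)
    rt_c, rt_b = np.array(rt_control), np.array(rt_blink)
    acc_c, acc_b = np.array(acc_control), np.array(acc_blink)
    out = {
        "n_control": len(rt_c),
        "n_blink": len(rt_b),
        "rt_control_mean": float(rt_c.mean()) if len(rt_c) else float("nan"),
        "rt_blink_mean": float(rt_b.mean()) if len(rt_b) else float("nan"),
        "accuracy_control_mean": float(acc_c.mean()) if len(acc_c) else float("nan"),
        "accuracy_blink_mean": float(acc_b.mean()) if len(acc_b) else float("nan"),
    }
    if len(rt_c) > 1 and len(rt_b) > 1:
        out["rt_p_one_tailed"] = float(
            stats.ttest_ind(rt_b, rt_c, equal_var=False, alternative="less").pvalue
        )
        out["accuracy_p_two_tailed"] = float(
            stats.ttest_ind(acc_b, acc_c, equal_var=False).pvalue
        )
    if len(acc_b) > 2:
        rho, p = stats.spearmanr(blink_times, acc_b)
        out["blinktime_accuracy_spearman"] = float(rho)
        out["blinktime_accuracy_p"] = float(p)
    return out


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _summary_row(result: MotorPotentialResult) -> dict:
    return {
        "condition": result.condition,
        "n_neurons": result.n_neurons,
        "mean_delay_post_ms": result.mean_delay_post,
        "mean_delay_pre_ms": result.mean_delay_pre,
        "significance_onset_ms": result.significance_onset,
    }


def run_full_analysis(config: RunConfig) -> dict:
    """Generate (or load) sessions, run every analysis stage, and assemble the
    run report.  Deterministic given the seeds in `config`; writes CSV tables
    and a JSON summary when `config.out_dir` is set."""
    t_start = time_mod.time()
    stage = "load"
    try:
        if config.input_dirs:
            from .io import read_session

            sessions: list[Session] = [read_session(d) for d in config.input_dirs]
        else:
            stage = "generate"
            sessions = generate_population(config.generator, config.n_neurons, base_seed=config.seed)

        stage = "preprocess"
        processed = [sp.process_session(s, variant=config.variant) for s in sessions]

        stage = "behavior"
        behavior = behavioral_summary(processed)

        stage = "motor_potential_control"
        control = population_motor_potential(
            processed,
            "control",
            movement_window=config.movement_window,
            lag_range=config.lag_range,
            post_window=config.post_window,
            n_shuffles=config.n_shuffles,
            seed=config.seed,
            fisher_z=config.fisher_z,
        )

        blink = None
        has_blink = any(p.inclusion and p.inclusion.in_motor_potential_set for p in processed)
        if has_blink:
            stage = "motor_potential_blink"
            blink = population_motor_potential(
                processed,
                "blink",
                movement_window=config.movement_window,
                lag_range=config.lag_range,
                post_window=config.post_window,
                pre_window=config.pre_window,
                n_shuffles=config.n_shuffles,
                seed=config.seed + 1,
                fisher_z=config.fisher_z,
            )

        threshold = None
        if any(p.inclusion and p.inclusion.in_threshold_set for p in processed):
            stage = "threshold"
            threshold = threshold_analysis(processed)

        rates = None
        if has_blink:
            stage = "accumulation"
            rates = accumulation_analysis(processed, n_pseudo=config.n_pseudo, seed=config.seed)
    except Exception:
        log.exception("run failed during stage %r", stage)
        raise

    cfg_dict = {
        **dataclasses.asdict(config.generator),
        "n_neurons": config.n_neurons,
        "seed": config.seed,
        "variant": config.variant,
    }
    cfg_hash = hashlib.sha256(json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest()[:16]

    report: dict = {
        "provenance": {"config_hash": cfg_hash, "seed": config.seed, "elapsed_s": round(time_mod.time() - t_start, 2)},
        "behavior": behavior,
        "motor_potential": {"control": _summary_row(control)},
        "blink_sections_present": blink is not None,
    }
    if blink is not None:
        report["motor_potential"]["blink"] = _summary_row(blink)
        report["motor_potential"]["pre_post_comparison"] = pre_post_delay_comparison(
            blink.delay_trace, config.pre_window, config.post_window
        )
    if threshold is not None:
        report["threshold"] = {
            "bins": [dataclasses.asdict(b) for b in threshold.bins],
            # classification windows are labeled by their right edge (the class
            # at time t uses only activity before t), so the class at -10 ms
            # reads the [-20, -10) window
            "proportion_lower_at_minus10": float(
                threshold.proportions["lower"][
                    [i for i, b in enumerate(init.THRESHOLD_BINS) if b[1] == -10][0]
                ]
            ),
        }
    if rates is not None:
        report["accumulation"] = dataclasses.asdict(rates["comparison"])

    if config.out_dir:
        _write_outputs(Path(config.out_dir), report, control, blink, threshold, rates)
    return report


def _write_outputs(out: Path, report: dict, control, blink, threshold, rates) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for result in (control, blink):
        if result is None:
            continue
        tag = result.condition
        pd.DataFrame(
            result.pop_map.corr, index=result.pop_map.movement_time, columns=result.pop_map.lags
        ).to_csv(out / f"correlation_map_{tag}.csv")
        pd.DataFrame(
            {
                "movement_time": result.delay_trace.movement_time,
                "optimal_delay": result.delay_trace.optimal_delay,
                "significant": result.bootstrap.significant,
                "correlation": result.bootstrap.actual,
            }
        ).to_csv(out / f"delay_trace_{tag}.csv", index=False)
    if threshold is not None:
        pd.DataFrame([dataclasses.asdict(b) for b in threshold.bins]).to_csv(
            out / "threshold_bins.csv", index=False
        )
        pd.DataFrame(threshold.classes).to_csv(out / "threshold_classes.csv", index=False)
    if rates is not None:
        pd.DataFrame(
            [
                {
                    "condition": f.condition,
                    "rate_pre": f.rate_pre,
                    "rate_post": f.rate_post,
                    "modulation_index": f.modulation_index,
                }
                for f in rates["blink_fits"] + rates["surrogate_fits"]
            ]
        ).to_csv(out / "rate_fits.csv", index=False)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
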