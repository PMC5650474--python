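"""BREM templates, embedded-saccade detection, inclusion filtering, and
kinematic variables for blink-triggered movements.

The goal-directed saccade embedded in a blink-triggered movement is found
model-free: build the session's expected BREM velocity distribution
(instantaneous mean and s.d. per component from fixation-blink trials), then
take the first time an individual movement's velocity leaves the +/-2.5 s.d.
bounds and stays outside for at least 15 consecutive samples, independently
per component; the earlier component marks saccade onset.  Onset delays of
at least 20 ms relative to overall movement onset identify movements that
were triggered by the blink rather than already in flight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)

SD_MULTIPLIER = 2.5
MIN_RUN_SAMPLES = 15
TRIGGERED_DELAY_MS = 20.0
MIN_BLINK_TRIALS = 7
SD_FLOOR = 1e-3  # deg/s


@dataclass
class BREMTemplate:
    """Instantaneous mean / s.d. of BREM velocity per component, aligned to
    BREM movement onset."""

    time: np.ndarray  # ms from movement onset
    mean_h: np.ndarray
    mean_v: np.ndarray
    sd_h: np.ndarray
    sd_v: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("a BREM template needs at least 2 trials")
        if np.any(self.sd_h < 0) or np.any(self.sd_v < 0):
            raise ValueError("template s.d. must be non-negative")


@dataclass
class EmbeddedSaccadeOnset:
    """Detected goal-directed saccade onset within a blink-triggered movement."""

    onset_delay: float  # ms from overall movement onset
    component: str  # "horizontal" | "vertical"
    classification: str  # "early" (<20 ms) | "triggered" (>=20 ms)

    def __post_init__(self) -> None:
        if self.onset_delay < 0:
            raise ValueError("onset delay must be >= 0")


def build_brem_template(
    velocity_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    dt: float = 1.0,
    sd_floor: float = SD_FLOOR,
) -> BREMTemplate:
    """Pointwise mean and sample s.d. of BREM velocities aligned to onset.

    `velocity_pairs` are (horizontal, vertical) traces already aligned to each
    BREM's detected movement onset; they are truncated to the shortest common
    support.  Zero s.d. at any sample is floored at `sd_floor` with a logged
    warning so the +/-2.5 s.d. bounds stay usable.
    """
    if len(velocity_pairs) < 2:
        raise ValueError("need at least 2 BREM trials to build a template")
    n = min(len(h) for h, _ in velocity_pairs)
    hs = np.stack([h[:n] for h, _ in velocity_pairs])
    vs = np.stack([v[:n] for _, v in velocity_pairs])
    sd_h = hs.std(axis=0, ddof=1)
    sd_v = vs.std(axis=0, ddof=1)
    if np.any(sd_h < sd_floor) or np.any(sd_v < sd_floor):
        log.warning("BREM template s.d. floored at %g deg/s at some samples", sd_floor)
    return BREMTemplate(
        time=np.arange(n) * dt,
        mean_h=hs.mean(axis=0),
        mean_v=vs.mean(axis=0),
        sd_h=np.maximum(sd_h, sd_floor),
        sd_v=np.maximum(sd_v, sd_floor),
        n_trials=len(velocity_pairs),
    )


def _sustained_excursions(deviation: np.ndarray, bound: np.ndarray, min_run: int) -> list[int]:
    """Start indices of runs where |deviation| > bound for >= min_run samples."""
    outside = np.abs(deviation) > bound
    starts = []
    count = 0
    for i, flag in enumerate(outside):
        count = count + 1 if flag else 0
        if count == min_run:
            starts.append(i - min_run + 1)
    return starts


def detect_embedded_saccade(
    h_vel: np.ndarray,
    v_vel: np.ndarray,
    template: BREMTemplate,
    sd_multiplier: float = SD_MULTIPLIER,
    min_run: int = MIN_RUN_SAMPLES,
    min_saccade_speed: Optional[float] = 80.0,
    speed_check_ms: float = 10.0,
) -> Optional[EmbeddedSaccadeOnset]:
    """Find the embedded saccade onset in a movement aligned to its own onset.

    Velocities must be on the template grid starting at overall movement
    onset.  Beyond the template support the last defined bound is reused.
    Returns None when neither component shows a qualifying excursion (the
    trial is excluded downstream).

    Candidate onsets (per-component sustained excursions beyond the
    +/-2.5 s.d. bounds, earliest first) must be followed within
    `speed_check_ms` by a residual vectorial speed of at least
    `min_saccade_speed` -- a goal-directed saccade is a high-velocity
    movement, so a sustained excursion that stays slow is a spurious trigger
    on drift or leaked premotor activity.  Rejected candidates are logged;
    set `min_saccade_speed=None` to disable the plausibility check.
    """
    n = len(h_vel)
    candidates: list[tuple[int, str]] = []
    means, sds = {}, {}
    for name, vel, mean, sd in (
        ("horizontal", h_vel, template.mean_h, template.sd_h),
        ("vertical", v_vel, template.mean_v, template.sd_v),
    ):
        m = np.zeros(n)
        s = np.full(n, sd[-1] if len(sd) else SD_FLOOR)
        k = min(n, len(mean))
        m[:k] = mean[:k]
        s[:k] = sd[:k]
        if n > k:
            s[k:] = sd[k - 1]
        means[name], sds[name] = m, s
        for idx in _sustained_excursions(vel - m, sd_multiplier * s, min_run):
            candidates.append((idx, name))
    if not candidates:
        return None
    candidates.sort()

    dt = float(template.time[1] - template.time[0]) if len(template.time) > 1 else 1.0
    res_speed = np.hypot(h_vel - means["horizontal"], v_vel - means["vertical"])
    chosen = None
    for idx, component in candidates:
        if min_saccade_speed is not None:
            j = min(n, idx + int(round(speed_check_ms / dt)) + 1)
            if res_speed[idx:j].max() < min_saccade_speed:
                log.info(
                    "excursion at %.0f ms stays below %.0f deg/s; spurious trigger skipped",
                    idx * dt,
                    min_saccade_speed,
                )
                continue
        chosen = (idx, component)
        break
    if chosen is None:
        return None
    idx, component = chosen
    delay = idx * dt
    classification = "triggered" if delay >= TRIGGERED_DELAY_MS else "early"
    return EmbeddedSaccadeOnset(onset_delay=delay, component=component, classification=classification)


@dataclass
class InclusionResult:
    """Per-neuron analysis-set membership after the trial-count filters."""

    in_threshold_set: bool  # >= 7 blink trials (all blink trials kept)
    in_motor_potential_set: bool  # >= 7 blink trials with onset delay >= 20 ms
    blink_trial_ids: list[int]  # all detected blink trials
    triggered_trial_ids: list[int]  # the onset-delay >= 20 ms subset


def apply_inclusion_criteria(
    detections: dict[int, Optional[EmbeddedSaccadeOnset]],
    min_trials: int = MIN_BLINK_TRIALS,
) -> InclusionResult:
    """Apply the trial-count filters to one neuron's blink-trial detections.

    `detections` maps blink trial id -> detection (None when no embedded
    saccade was found; those trials are excluded from every set).
    """
    detected = {tid: d for tid, d in detections.items() if d is not None}
    triggered = [tid for tid, d in detected.items() if d.classification == "triggered"]
    return InclusionResult(
        in_threshold_set=len(detected) >= min_trials,
        in_motor_potential_set=len(triggered) >= min_trials,
        blink_trial_ids=sorted(detected),
        triggered_trial_ids=sorted(triggered),
    )


# ---------------------------------------------------------------------------
# kinematic variables
# ---------------------------------------------------------------------------

def vectorial_velocity(h_vel: np.ndarray, v_vel: np.ndarray) -> np.ndarray:
    """Pythagorean vectorial speed, pointwise."""
    h_vel = np.asarray(h_vel, dtype=float)
    v_vel = np.asarray(v_vel, dtype=float)
    if h_vel.shape != v_vel.shape:
        raise ValueError("component arrays must have equal length")
    return np.hypot(h_vel, v_vel)


def residual_velocity(
    h_vel: np.ndarray,
    v_vel: np.ndarray,
    template: BREMTemplate,
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the session's mean BREM template, componentwise.

    Traces are aligned to overall movement onset; beyond the template support
    nothing is subtracted.
    """
    n = len(h_vel)
    res_h = np.array(h_vel, dtype=float)
    res_v = np.array(v_vel, dtype=float)
    k = min(n, len(template.mean_h))
    res_h[:k] -= template.mean_h[:k]
    res_v[:k] -= template.mean_v[:k]
    return res_h, res_v


def project_on_goal(
    res_h: np.ndarray,
    res_v: np.ndarray,
    goal_direction_deg: float,
) -> np.ndarray:
    """Signed scalar projection of the (residual) velocity on the goal direction.

    Equals |v| cos(theta) with theta the angle between the instantaneous
    vector and the saccade-goal direction; negative when the eye moves away
    from the goal, and 0 for a zero-magnitude vector.
    """
    th = np.radians(goal_direction_deg)
    return np.asarray(res_h) * np.cos(th) + np.asarray(res_v) * np.sin(th)


def goal_direction(fixation: tuple[float, float], target: tuple[float, float]) -> float:
    """Direction (deg) from the initial fixation position to the target."""
    dx = target[0] - fixation[0]
    dy = target[1] - fixation[1]
    if dx == 0 and dy == 0:
        raise ValueError("target coincides with fixation; goal direction undefined")
    return float(np.degrees(np.arctan2(dy, dx)))


def endpoint_accuracy(
    endpoint: tuple[float, float],
    target: tuple[float, float],
    fixation: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Euclidean endpoint error normalized by target eccentricity."""
    ecc = float(np.hypot(target[0] - fixation[0], target[1] - fixation[1]))
    if ecc == 0:
        raise ValueError("zero target eccentricity; normalized error undefined")
    err = float(np.hypot(endpoint[0] - target[0], endpoint[1] - target[1]))
    return err / ecc
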