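"""Shared in-memory containers for trials, sessions, and derived signals.

All times are in milliseconds on a uniform grid (1 kHz by default), positions
in degrees, velocities in deg/s, firing rates in spikes/s.  A session holds
the data recorded alongside one neuron: fixation-blink trials (BREM only),
control delayed-saccade trials, and blink-perturbation trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CONTROL = "control"
BLINK = "blink"
BREM = "brem"


@dataclass
class EyeTrace:
    """Uniformly sampled eye position (and optionally velocity) for one trial."""

    time: np.ndarray  # ms
    h_pos: np.ndarray  # deg
    v_pos: np.ndarray  # deg
    h_vel: Optional[np.ndarray] = None  # deg/s
    v_vel: Optional[np.ndarray] = None  # deg/s

    def __post_init__(self) -> None:
        n = len(self.time)
        if len(self.h_pos) != n or len(self.v_pos) != n:
            raise ValueError("position arrays must match the time grid length")
        for v in (self.h_vel, self.v_vel):
            if v is not None and len(v) != n:
                raise ValueError("velocity arrays must match the time grid length")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class TrialRecord:
    """One trial: eye trace, task events, spike times, and condition labels.

    ``blink_on`` is only set on blink and fixation-BREM trials.  ``movement_on``
    and ``movement_off`` are filled in by movement detection, not the task.
    """

    trial_id: int
    condition: str  # CONTROL | BLINK | BREM
    target: Optional[tuple[float, float]]  # (x, y) deg; None on BREM trials
    eye: EyeTrace
    spikes: np.ndarray  # spike times, ms
    target_on: Optional[float] = None
    go_cue: Optional[float] = None
    blink_on: Optional[float] = None
    movement_on: Optional[float] = None
    movement_off: Optional[float] = None

    def __post_init__(self) -> None:
        if self.condition not in (CONTROL, BLINK, BREM):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.blink_on is not None and self.condition == CONTROL:
            raise ValueError("blink_on must not be set on control trials")
        if (
            self.target_on is not None
            and self.go_cue is not None
            and not self.target_on < self.go_cue
        ):
            raise ValueError("event ordering violated: target_on < go_cue required")


@dataclass
class SpikeDensity:
    """Spike density function on a ms grid (Gaussian-kernel smoothed rate)."""

    time: np.ndarray  # ms
    rate: np.ndarray  # spikes/s
    kernel_width: float  # Gaussian s.d., ms


@dataclass
class SaccadeEvent:
    """A detected movement with the component that determined its onset."""

    onset: float  # ms
    offset: float  # ms
    component_of_onset: str  # "horizontal" | "vertical"
    peak_velocity: float  # deg/s, vectorial
    amplitude: float  # deg, displacement between onset and offset

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError("movement onset must precede offset")


@dataclass
class TrialTruth:
    """Ground truth recorded by the generator for one trial."""

    trial_id: int
    condition: str
    rate_scale: float  # per-trial multiplicative scale on preparatory drive
    slope_pre: float  # spikes/s/ms, effective pre-blink accumulation slope
    slope_post: float  # spikes/s/ms, effective post-blink slope (== pre on control)
    gate_open: Optional[float] = None  # ms; blink time (blink) or OPN pause (control)
    saccade_onset: Optional[float] = None  # ms; onset per the 50 deg/s convention
    profile_start: Optional[float] = None  # ms; analytic start of the saccadic profile
    movement_onset: Optional[float] = None  # ms; blink trials: overall movement onset
    onset_delay: Optional[float] = None  # ms; blink trials: saccade re movement onset
    reaction_time: Optional[float] = None  # ms from GO cue


@dataclass
class GroundTruth:
    """Session-level ground truth: injected parameters plus per-trial records."""

    efference_delay: float  # ms
    threshold_rate: float  # spikes/s
    blink_threshold_fraction: float
    post_blink_slope_multiplier: float
    trials: dict[int, TrialTruth] = field(default_factory=dict)


@dataclass
class Session:
    """All trials recorded with one neuron, plus ground truth when synthetic."""

    session_id: str
    trials: list[TrialRecord]
    ground_truth: Optional[GroundTruth] = None

    def by_condition(self, condition: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.condition == condition]

    @property
    def control_trials(self) -> list[TrialRecord]:
        return self.by_condition(CONTROL)

    @property
    def blink_trials(self) -> list[TrialRecord]:
        return self.by_condition(BLINK)

    @property
    def brem_trials(self) -> list[TrialRecord]:
        return self.by_condition(BREM)
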