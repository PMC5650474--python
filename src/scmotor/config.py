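"""Generator configuration: the task, kinematic, and neural coupling parameters.

The defaults describe a delayed saccade task with an enforced 500-1200 ms delay
period, air-puff blinks delivered 100-250 ms after the GO cue on perturbation
trials, and a premotor neuron whose accumulating drive reaches an initiation
criterion to trigger the saccade.  Eye velocity is a gain-scaled, delayed copy
of the neuron's motor drive (nominal efference delay 12 ms), gated by an
OPN-like inhibition that a blink removes early.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml


class ConfigError(ValueError):
    """Raised when a generator configuration field is invalid (names the field)."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"invalid config field {field_name!r}: {message}")


@dataclass
class GeneratorConfig:
    # --- session structure -------------------------------------------------
    sampling_rate: float = 1000.0  # samples/s
    n_control_trials: int = 48
    n_blink_trials: int = 36
    n_brem_trials: int = 20
    seed: int = 0

    # --- task timing (ms) ---------------------------------------------------
    target_onset: float = 300.0  # fixed fixation period before target appears
    delay_range: tuple[float, float] = (500.0, 1200.0)  # GO-cue delay after target
    blink_window: tuple[float, float] = (100.0, 250.0)  # blink time after GO

    # --- accumulator / initiation ------------------------------------------
    baseline_rate: float = 15.0  # spikes/s
    threshold_rate: float = 240.0  # spikes/s; control initiation criterion
    opn_lead: float = 20.0  # ms gate-to-saccade lead under natural initiation
    prep_slope_mean: float = 0.90  # spikes/s/ms
    prep_slope_sd: float = 0.18
    rt_mean: Optional[float] = None  # if set, slopes derived from an RT distribution
    rt_sd: float = 45.0
    blink_threshold_fraction: float = 0.8  # blink saccades launch at this x criterion
    post_blink_slope_multiplier: float = 3.0  # accumulation acceleration after blink

    # --- activity variability ----------------------------------------------
    rate_scale_sd: float = 0.25  # lognormal sigma of per-trial preparatory scale
    rate_noise_sd: float = 0.50  # multiplicative smooth noise on preparatory drive
    burst_noise_sd: float = 0.20  # multiplicative smooth noise on the motor burst
    burst_gain_jitter_sd: float = 0.06  # per-trial burst gain jitter
    rate_noise_smooth_ms: float = 4.0  # s.d. of the Gaussian smoothing the noise

    # --- kinematics ---------------------------------------------------------
    efference_delay: float = 12.0  # ms; rate-to-velocity conduction delay
    burst_gain: float = 1.0  # (deg/s) per (spike/s) during the burst
    leak_gain: float = 0.10  # (deg/s) per (spike/s) for pre-saccade leakage
    target_eccentricity: float = 15.0  # deg
    target_direction: float = 45.0  # deg
    vmax: float = 700.0  # deg/s; main-sequence V(A) = vmax (1 - exp(-A / a0))
    a0: float = 9.0  # deg
    saccade_direction_jitter: float = 4.0  # deg s.d. per trial
    position_noise_sd: float = 0.008  # deg, white measurement noise on position
    drift_pos_sd: float = 0.40  # deg, slow fixational drift excursion per component
    drift_smooth_ms: float = 25.0  # correlation scale of the drift

    # --- blink-related eye movement (BREM) ----------------------------------
    brem_amplitude_mean: float = 4.0  # deg, loop excursion scale
    brem_gain_sd: float = 0.08  # per-trial multiplicative gain jitter
    brem_noise_sd: float = 8.0  # deg/s, smooth additive noise per component
    brem_noise_smooth_ms: float = 5.0
    brem_duration: float = 180.0  # ms, template support

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate", "must be > 0")
        if self.efference_delay <= 0:
            raise ConfigError("efference_delay", "must be > 0")
        if not 0 < self.blink_threshold_fraction <= 1:
            raise ConfigError("blink_threshold_fraction", "must be in (0, 1]")
        if self.post_blink_slope_multiplier < 1:
            raise ConfigError("post_blink_slope_multiplier", "must be >= 1")
        for name in ("n_control_trials", "n_blink_trials", "n_brem_trials"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be >= 0")
        lo, hi = self.delay_range
        if not 0 < lo <= hi:
            raise ConfigError("delay_range", "must be an increasing positive pair")
        lo, hi = self.blink_window
        if not 0 < lo <= hi:
            raise ConfigError("blink_window", "must be an increasing positive pair")
        # blinks must land within the plausible reaction-time range, i.e. before
        # the earliest natural saccades would typically have been triggered
        if hi > 600:
            raise ConfigError("blink_window", "upper bound beyond plausible RT range")
        if self.threshold_rate <= 0:
            raise ConfigError("threshold_rate", "must be > 0")
        if self.prep_slope_mean <= 0:
            raise ConfigError("prep_slope_mean", "must be > 0")
        if self.target_eccentricity <= 0:
            raise ConfigError("target_eccentricity", "must be > 0")
        if self.brem_duration <= 0:
            raise ConfigError("brem_duration", "must be > 0")

    @property
    def dt(self) -> float:
        """Sampling interval in ms."""
        return 1000.0 / self.sampling_rate

    # --- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["delay_range"] = list(d["delay_range"])
        d["blink_window"] = list(d["blink_window"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown field")
        d = dict(d)
        for key in ("delay_range", "blink_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)
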