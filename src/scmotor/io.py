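"""Session bundles on disk.

A bundle is one directory per session:

* ``trials.csv``  -- trial id, condition, target x/y (deg), event times (ms)
* ``eye.csv``     -- long format: trial id, time (ms), horizontal and
  vertical position (deg)
* ``spikes.csv``  -- trial id, spike time (ms)
* ``ground_truth.json`` -- generator ground truth (synthetic sessions only)
* ``config.yaml`` -- the generator configuration (synthetic sessions only)

All times are trial-relative, 0-based, in milliseconds; velocities are
derived downstream from positions.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .containers import EyeTrace, GroundTruth, Session, TrialRecord, TrialTruth


def write_session(session: Session, out_dir: str | Path, config: Optional[GeneratorConfig] = None) -> Path:
    out = Path(out_dir) / session.session_id
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    eye_frames = []
    spike_rows = []
    for tr in session.trials:
        rows.append(
            {
                "trial_id": tr.trial_id,
                "condition": tr.condition,
                "target_x": tr.target[0] if tr.target else np.nan,
                "target_y": tr.target[1] if tr.target else np.nan,
                "target_on": tr.target_on,
                "go_cue": tr.go_cue,
                "blink_on": tr.blink_on,
            }
        )
        eye_frames.append(
            pd.DataFrame(
                {
                    "trial_id": tr.trial_id,
                    "time": tr.eye.time,
                    "h_pos": np.round(tr.eye.h_pos, 5),
                    "v_pos": np.round(tr.eye.v_pos, 5),
                }
            )
        )
        for s in tr.spikes:
            spike_rows.append({"trial_id": tr.trial_id, "spike_time": round(float(s), 3)})

    pd.DataFrame(rows).to_csv(out / "trials.csv", index=False)
    pd.concat(eye_frames, ignore_index=True).to_csv(out / "eye.csv", index=False)
    pd.DataFrame(spike_rows, columns=["trial_id", "spike_time"]).to_csv(out / "spikes.csv", index=False)

    if session.ground_truth is not None:
        gt = session.ground_truth
        payload = {
            "efference_delay": gt.efference_delay,
            "threshold_rate": gt.threshold_rate,
            "blink_threshold_fraction": gt.blink_threshold_fraction,
            "post_blink_slope_multiplier": gt.post_blink_slope_multiplier,
            "trials": {str(k): dataclasses.asdict(v) for k, v in gt.trials.items()},
        }
        (out / "ground_truth.json").write_text(json.dumps(payload, indent=1))
    if config is not None:
        config.to_yaml(out / "config.yaml")
    return out


def read_session(session_dir: str | Path) -> Session:
    d = Path(session_dir)
    trials_df = pd.read_csv(d / "trials.csv")
    eye_df = pd.read_csv(d / "eye.csv")
    spikes_df = pd.read_csv(d / "spikes.csv")

    trials = []
    for _, row in trials_df.iterrows():
        tid = int(row["trial_id"])
        eye = eye_df[eye_df["trial_id"] == tid]
        spikes = spikes_df.loc[spikes_df["trial_id"] == tid, "spike_time"].to_numpy(dtype=float)
        target = None
        if np.isfinite(row["target_x"]) and np.isfinite(row["target_y"]):
            target = (float(row["target_x"]), float(row["target_y"]))

        def _opt(name: str) -> Optional[float]:
            v = row[name]
            return float(v) if np.isfinite(v) else None

        trials.append(
            TrialRecord(
                trial_id=tid,
                condition=str(row["condition"]),
                target=target,
                eye=EyeTrace(
                    time=eye["time"].to_numpy(dtype=float),
                    h_pos=eye["h_pos"].to_numpy(dtype=float),
                    v_pos=eye["v_pos"].to_numpy(dtype=float),
                ),
                spikes=np.sort(spikes),
                target_on=_opt("target_on"),
                go_cue=_opt("go_cue"),
                blink_on=_opt("blink_on"),
            )
        )

    ground_truth = None
    gt_path = d / "ground_truth.json"
    if gt_path.exists():
        payload = json.loads(gt_path.read_text())
        ground_truth = GroundTruth(
            efference_delay=payload["efference_delay"],
            threshold_rate=payload["threshold_rate"],
            blink_threshold_fraction=payload["blink_threshold_fraction"],
            post_blink_slope_multiplier=payload["post_blink_slope_multiplier"],
            trials={int(k): TrialTruth(**v) for k, v in payload["trials"].items()},
        )
    return Session(session_id=d.name, trials=trials, ground_truth=ground_truth)
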