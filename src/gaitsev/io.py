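"""CSV/JSON serialisation of cohort, recordings and derived tables.

Recordings use a long format with one row per sample and segment:
``time_s, trial, segment, side, gyro_x_dps, gyro_y_dps, gyro_z_dps,
acc_x_mps2, acc_y_mps2, acc_z_mps2``.  The cohort manifest and feature
tables are plain CSV; ground truth (true gait parameters and per-trial
event lists) travels in a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GaitParameterSet, GroupLabel, SubjectProfile
from .simulate import ImuRecording, TrialTrace

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_ground_truth_json",
    "read_ground_truth_json",
]

_SEG_SPLIT = {"pelvis": ("pelvis", "C")}
for stem in ("thigh", "shank", "foot"):
    for side in ("L", "R"):
        _SEG_SPLIT[f"{stem}_{side}"] = (stem, side)
_SEG_JOIN = {v: k for k, v in _SEG_SPLIT.items()}


def write_recording_csv(recording: ImuRecording, path: str | Path) -> None:
    frames = []
    for ti, trial in enumerate(recording.trials):
        for seg, gyro in trial.gyro_dps.items():
            stem, side = _SEG_SPLIT[seg]
            acc = trial.accel_mps2[seg]
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": trial.time_s,
                        "trial": ti,
                        "segment": stem,
                        "side": side,
                        "gyro_x_dps": gyro[:, 0],
                        "gyro_y_dps": gyro[:, 1],
                        "gyro_z_dps": gyro[:, 2],
                        "acc_x_mps2": acc[:, 0],
                        "acc_y_mps2": acc[:, 1],
                        "acc_z_mps2": acc[:, 2],
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_recording_csv(
    path: str | Path, subject_id: str = "", sampling_rate_hz: float | None = None
) -> ImuRecording:
    df = pd.read_csv(path)
    trials = []
    for ti in sorted(df["trial"].unique()):
        sub = df[df["trial"] == ti]
        gyro, accel = {}, {}
        time = None
        for (stem, side), block in sub.groupby(["segment", "side"]):
            seg = _SEG_JOIN[(stem, side)]
            block = block.sort_values("time_s")
            gyro[seg] = block[["gyro_x_dps", "gyro_y_dps", "gyro_z_dps"]].to_numpy()
            accel[seg] = block[["acc_x_mps2", "acc_y_mps2", "acc_z_mps2"]].to_numpy()
            time = block["time_s"].to_numpy()
        trials.append(TrialTrace(time_s=time, gyro_dps=gyro, accel_mps2=accel))
    if sampling_rate_hz is None:
        dt = np.diff(trials[0].time_s[:2])[0]
        sampling_rate_hz = 1.0 / dt
    return ImuRecording(
        subject_id=subject_id,
        sampling_rate_hz=float(sampling_rate_hz),
        trials=trials,
        ground_truth_events=[[] for _ in trials],
    )


def write_cohort_csv(profiles: list[SubjectProfile], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": p.subject_id,
                "group": p.group.value,
                "cdr": p.group.cdr,
                "age": p.age,
                "sex": p.sex,
                "height_cm": p.height_cm,
                "weight_kg": p.weight_kg,
                "bmi": p.bmi,
                "leg_length_m": p.leg_length_m,
            }
            for p in profiles
        ]
    ).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth_json(profiles: list[SubjectProfile], path: str | Path) -> None:
    payload = {
        p.subject_id: {
            "group": p.group.value,
            "true_params": p.true_params.as_dict(),
            "warnings": p.warnings,
        }
        for p in profiles
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth_json(path: str | Path) -> dict[str, SubjectProfile]:
    raw = json.loads(Path(path).read_text())
    out = {}
    for sid, rec in raw.items():
        params = GaitParameterSet(**rec["true_params"])
        out[sid] = {
            "group": GroupLabel(rec["group"]),
            "true_params": params,
            "warnings": rec.get("warnings", []),
        }
    return out
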