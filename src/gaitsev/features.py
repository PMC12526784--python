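"""Extraction of the 11 spatiotemporal and kinematic gait parameters.

For each subject the pipeline runs filter -> event detection -> cycle
segmentation -> sensor fusion -> joint angles, pools valid cycles across
all trials and both sides, and summarises:

gait cycle time (s), stance and swing phase (% of cycle), walking velocity
(m/s), cadence (steps/min), initial/single/terminal support (% of cycle),
and sagittal hip/knee/ankle range of motion (deg).

Formulas: cycle time is the interval between consecutive same-side heel
strikes; step time the interval between alternating-side heel strikes;
cadence = 60 / step time; velocity = step length / step time with step
length from the pendulum estimator on the shank sweep; stance% is
(toe-off - heel strike) / cycle time; initial double support runs from
heel strike to the contralateral toe-off, terminal double support from the
contralateral heel strike to the ipsilateral toe-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import SubjectProfile, sample_cohort
from .config import CohortConfig, PipelineConfig
from .kinematics import JOINT_SEGMENTS, rom_per_cycle, step_lengths_per_cycle
from .signal_prep import FilterSpec, detect_gait_events, lowpass_filter, segment_cycles
from .simulate import SAGITTAL_GYRO_AXIS, ImuRecording, synthesize_recording

__all__ = [
    "FEATURE_NAMES",
    "SubjectFeatures",
    "extract_features",
    "spatiotemporal_params",
    "joint_angle_series",
    "build_feature_table",
]

#: The 11 gait features, in the study's table order.
FEATURE_NAMES = (
    "gait_cycle_time",
    "stance_pct",
    "swing_pct",
    "velocity",
    "cadence",
    "initial_double_support_pct",
    "single_support_pct",
    "terminal_double_support_pct",
    "hip_rom",
    "knee_rom",
    "ankle_rom",
)


@dataclass
class SubjectFeatures:
    """Pooled per-cycle measurements and their subject-level summary."""

    subject_id: str
    values: dict[str, float]
    n_cycles: int
    rejected_cycles: int = 0
    warnings: list[str] = field(default_factory=list)


def _agg(values: list[float], how: str) -> float:
    if not values:
        return float("nan")
    arr = np.asarray(values, dtype=float)
    return float(np.median(arr)) if how == "median" else float(arr.mean())


@dataclass
class _CycleValues:
    """Raw per-cycle / per-step measurement pools (trial-poolable)."""

    durations: list[float] = field(default_factory=list)
    stances: list[float] = field(default_factory=list)
    ids: list[float] = field(default_factory=list)
    tds: list[float] = field(default_factory=list)
    ss: list[float] = field(default_factory=list)
    step_times: list[float] = field(default_factory=list)
    rejected: int = 0

    def extend(self, other: "_CycleValues") -> None:
        for name in ("durations", "stances", "ids", "tds", "ss", "step_times"):
            getattr(self, name).extend(getattr(other, name))
        self.rejected += other.rejected


def _collect_cycle_values(cycles_left, cycles_right) -> _CycleValues:
    """Per-cycle temporal values for one trial (single common time base)."""
    out = _CycleValues()
    for c in list(cycles_left) + list(cycles_right):
        ids = tds = None
        if c.contra_toe_off is not None:
            ids = 100.0 * (c.contra_toe_off - c.start_hs) / c.duration
        if c.contra_heel_strike is not None:
            tds = 100.0 * (c.toe_off - c.contra_heel_strike) / c.duration
        if (ids is not None and ids < 0) or (tds is not None and tds < 0):
            out.rejected += 1
            continue
        out.durations.append(c.duration)
        out.stances.append(c.stance_pct)
        if ids is not None:
            out.ids.append(ids)
        if tds is not None:
            out.tds.append(tds)
        if ids is not None and tds is not None:
            out.ss.append(c.stance_pct - ids - tds)

    hs_times = sorted(
        {(c.start_hs, c.side) for c in cycles_left}
        | {(c.end_hs, c.side) for c in cycles_left}
        | {(c.start_hs, c.side) for c in cycles_right}
        | {(c.end_hs, c.side) for c in cycles_right}
    )
    out.step_times = [
        b[0] - a[0]
        for a, b in zip(hs_times[:-1], hs_times[1:])
        if a[1] != b[1] and b[0] - a[0] > 0
    ]
    return out


def _summarise(pool: _CycleValues, step_lengths_m, aggregate: str) -> dict[str, float]:
    stance = _agg(pool.stances, aggregate)
    step_time = _agg(pool.step_times, aggregate)
    out = {
        "gait_cycle_time": _agg(pool.durations, aggregate),
        "stance_pct": stance,
        "swing_pct": 100.0 - stance,
        "cadence": 60.0 / step_time if np.isfinite(step_time) and step_time > 0 else float("nan"),
        "initial_double_support_pct": _agg(pool.ids, aggregate),
        "terminal_double_support_pct": _agg(pool.tds, aggregate),
        "single_support_pct": _agg(pool.ss, aggregate),
        "step_time": step_time,
        "rejected_cycles": float(pool.rejected),
    }
    if step_lengths_m is not None and len(step_lengths_m) and np.isfinite(step_time):
        sl = _agg(list(step_lengths_m), aggregate)
        out["step_length"] = sl
        out["velocity"] = sl / step_time
    else:
        out["step_length"] = float("nan")
        out["velocity"] = float("nan")
    return out


def spatiotemporal_params(
    cycles_left,
    cycles_right,
    step_lengths_m: np.ndarray | None = None,
    aggregate: str = "mean",
) -> dict[str, float]:
    """Temporal/spatial parameters from segmented cycles of both sides.

    All cycles must share one time base (one trial).  Returns the
    non-kinematic features plus step time/length (velocity is NaN when no
    step lengths are supplied); cycles with a negative support interval are
    rejected and counted under ``"rejected_cycles"``.
    """
    return _summarise(
        _collect_cycle_values(cycles_left, cycles_right), step_lengths_m, aggregate
    )


def _fused_angles(recording: ImuRecording, pipeline: PipelineConfig):
    """Filtered sagittal gyro and fused orientation angles per trial.

    Equal-length trials are filtered and fused in one vectorized pass; the
    per-column math is identical to :func:`gaitsev.kinematics.
    complementary_filter` (trapezoidal gyro integration, accelerometer
    inclination, initial angle from the calibration-window mean).
    """
    from scipy.signal import lfilter

    fs = recording.sampling_rate_hz
    spec = FilterSpec(fs, pipeline.filter_cutoff_hz, pipeline.filter_order)
    alpha = pipeline.alpha
    dt = 1.0 / fs
    trials = recording.trials
    same_len = len({len(tr) for tr in trials}) == 1
    batches = [trials] if same_len else [[tr] for tr in trials]
    for batch in batches:
        segs = list(batch[0].gyro_dps)
        m = len(segs)
        n = len(batch[0])
        rows: list[np.ndarray] = []  # channels-first for fast filtering
        for tr in batch:
            for seg in segs:
                rows.append(tr.gyro_dps[seg][:, SAGITTAL_GYRO_AXIS])
            for seg in segs:
                rows.append(tr.accel_mps2[seg][:, 0])
                rows.append(tr.accel_mps2[seg][:, 2])
        X = lowpass_filter(np.vstack(rows), spec, axis=-1)

        k = 3 * m  # filtered rows per trial
        gyro_idx = np.concatenate([np.arange(i * k, i * k + m) for i in range(len(batch))])
        ax_idx = np.concatenate(
            [i * k + m + 2 * np.arange(m) for i in range(len(batch))]
        )
        omega = X[gyro_idx]  # (channels, n)
        theta_acc = np.degrees(np.arctan2(X[ax_idx], X[ax_idx + 1]))

        t = np.arange(n) * dt
        lo, hi = pipeline.calibration_window_s
        win = (t >= lo) & (t <= hi)
        theta0 = theta_acc[:, win].mean(axis=1) if win.any() else theta_acc[:, 0]
        incr = 0.5 * (omega[:, 1:] + omega[:, :-1]) * dt
        u = alpha * incr + (1.0 - alpha) * theta_acc[:, 1:]
        fused, _ = lfilter(
            [1.0], [1.0, -alpha], u, axis=-1, zi=(alpha * theta0)[:, None]
        )
        theta_all = np.hstack([theta0[:, None], fused])

        for i in range(len(batch)):
            gyro_f = {seg: X[i * k + j] for j, seg in enumerate(segs)}
            theta = {seg: theta_all[i * m + j] for j, seg in enumerate(segs)}
            yield segs, gyro_f, theta


def extract_features(
    recording: ImuRecording,
    leg_length_m: float,
    pipeline: PipelineConfig | None = None,
) -> SubjectFeatures | None:
    """Run the full extraction pipeline on one subject's recording.

    Pools valid cycles over all trials and both sides; returns ``None`` when
    no valid cycle survives (the caller excludes the subject).
    """
    pipeline = pipeline or PipelineConfig()
    fs = recording.sampling_rate_hz
    pipeline.validate(fs)
    spec = FilterSpec(fs, pipeline.filter_cutoff_hz, pipeline.filter_order)

    pool = _CycleValues()
    n_cycles = 0
    step_lengths: list[float] = []
    roms: dict[str, list[float]] = {"hip": [], "knee": [], "ankle": []}

    for trial, angles in zip(recording.trials, _fused_angles(recording, pipeline)):
        segs, gyro_f, theta = angles
        n = len(trial)
        t = np.arange(n) / fs

        events = {
            side: detect_gait_events(
                gyro_f[f"foot_{side}"],
                fs,
                side=side,
                threshold_dps=pipeline.event_threshold_dps,
                min_separation_s=pipeline.min_separation_s,
            )
            for side in ("L", "R")
        }
        cycles = segment_cycles(events["L"], events["R"])
        if not cycles["L"] and not cycles["R"]:
            continue

        pool.extend(_collect_cycle_values(cycles["L"], cycles["R"]))
        n_cycles += len(cycles["L"]) + len(cycles["R"])
        lo, hi = pipeline.calibration_window_s
        calib = (t >= lo) & (t <= hi)
        for side in ("L", "R"):
            side_cycles = cycles[side]
            if not side_cycles:
                continue
            for joint, (prox, dist) in JOINT_SEGMENTS.items():
                prox_key = prox if prox == "pelvis" else f"{prox}_{side}"
                diff = theta[prox_key] - theta[f"{dist}_{side}"]
                angle = diff - diff[calib].mean()
                roms[joint].extend(
                    rom_per_cycle(t, angle, side_cycles, joint, side).rom_deg.tolist()
                )
            step_lengths.extend(
                step_lengths_per_cycle(
                    t, theta[f"shank_{side}"], side_cycles, leg_length_m
                ).tolist()
            )
    if n_cycles == 0:
        return None

    # subject level: aggregate per-cycle values pooled over trials and sides
    values = _summarise(pool, np.asarray(step_lengths), pipeline.aggregate)
    rejected = int(values.pop("rejected_cycles"))
    for joint in ("hip", "knee", "ankle"):
        values[f"{joint}_rom"] = _agg(roms[joint], pipeline.aggregate)
    return SubjectFeatures(
        subject_id=recording.subject_id,
        values=values,
        n_cycles=n_cycles,
        rejected_cycles=rejected,
        warnings=list(recording.warnings),
    )


def joint_angle_series(
    recording: ImuRecording,
    pipeline: PipelineConfig | None = None,
    trial: int = 0,
) -> pd.DataFrame:
    """Tidy joint-angle series for one trial: time_s, joint, side, angle_deg.

    Convenience export for plotting sagittal joint curves (e.g. knee motion
    across severity groups); angles are calibrated against the static
    standing window exactly as in feature extraction.
    """
    pipeline = pipeline or PipelineConfig()
    fs = recording.sampling_rate_hz
    pipeline.validate(fs)
    for i, (segs, _gyro, theta) in enumerate(_fused_angles(recording, pipeline)):
        if i == trial:
            n = len(theta[segs[0]])
            t = np.arange(n) / fs
            lo, hi = pipeline.calibration_window_s
            calib = (t >= lo) & (t <= hi)
            frames = []
            for joint, (prox, dist) in JOINT_SEGMENTS.items():
                for side in ("L", "R"):
                    prox_key = prox if prox == "pelvis" else f"{prox}_{side}"
                    diff = theta[prox_key] - theta[f"{dist}_{side}"]
                    frames.append(
                        pd.DataFrame(
                            {
                                "time_s": t,
                                "joint": joint,
                                "side": side,
                                "angle_deg": diff - diff[calib].mean(),
                            }
                        )
                    )
            return pd.concat(frames, ignore_index=True)
    raise IndexError(f"trial {trial} out of range")


def build_feature_table(
    config: CohortConfig | None = None,
    pipeline: PipelineConfig | None = None,
    seed: int | None = None,
    profiles: list[SubjectProfile] | None = None,
    recordings: dict[str, ImuRecording] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Simulate (or reuse) a cohort and assemble the feature table.

    Returns ``(table, excluded_subject_ids)``; the table has one row per
    subject with columns subject_id, group, cdr, the 11 features in fixed
    order, and no missing values.  Deterministic given config and seed.
    """
    config = config or CohortConfig()
    pipeline = pipeline or PipelineConfig()
    master = config.seed if seed is None else seed
    if profiles is None:
        profiles = sample_cohort(config, master)

    rows = []
    excluded: list[str] = []
    for prof in profiles:
        rec = (
            recordings[prof.subject_id]
            if recordings is not None
            else synthesize_recording(prof, config, master)
        )
        feats = extract_features(rec, prof.leg_length_m, pipeline)
        if feats is None or any(
            not np.isfinite(feats.values[f]) for f in FEATURE_NAMES
        ):
            excluded.append(prof.subject_id)
            continue
        row = {
            "subject_id": prof.subject_id,
            "group": prof.group.value,
            "cdr": prof.group.cdr,
        }
        row.update({f: feats.values[f] for f in FEATURE_NAMES})
        rows.append(row)
    table = pd.DataFrame(rows, columns=["subject_id", "group", "cdr", *FEATURE_NAMES])
    return table, excluded
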