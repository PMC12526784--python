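"""Signal conditioning and gait-event detection.

Raw gyro/accelerometer traces are low-pass filtered with a zero-phase
4th-order Butterworth at 20 Hz (gait dynamics live below that band), and
gait events are read off the foot sagittal angular velocity: heel strikes
are positive local maxima strictly exceeding +50 deg/s, toe-offs negative
local minima below -50 deg/s.  Cycles are delimited by consecutive
same-side heel strikes containing exactly one toe-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

__all__ = [
    "FilterSpec",
    "GaitEvent",
    "GaitCycle",
    "DataError",
    "lowpass_filter",
    "detect_gait_events",
    "segment_cycles",
]


class DataError(ValueError):
    """Raised for malformed input signals."""


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth low-pass specification."""

    sampling_rate_hz: float
    cutoff_hz: float = 20.0
    order: int = 4

    def __post_init__(self) -> None:
        if self.cutoff_hz >= self.sampling_rate_hz / 2.0:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must be below the Nyquist "
                f"frequency {self.sampling_rate_hz / 2.0} Hz"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


@dataclass(frozen=True)
class GaitEvent:
    time_s: float
    side: str  # "L" or "R"
    kind: str  # "heel_strike" or "toe_off"
    peak_dps: float


@dataclass
class GaitCycle:
    """One gait cycle: same-side heel strike to the next heel strike."""

    side: str
    start_hs: float
    toe_off: float
    end_hs: float
    contra_toe_off: float | None = None
    contra_heel_strike: float | None = None

    def __post_init__(self) -> None:
        if not self.start_hs < self.toe_off < self.end_hs:
            raise ValueError("cycle events must satisfy start < toe_off < end")

    @property
    def duration(self) -> float:
        return self.end_hs - self.start_hs

    @property
    def stance_pct(self) -> float:
        return 100.0 * (self.toe_off - self.start_hs) / self.duration


def lowpass_filter(series: np.ndarray, spec: FilterSpec, axis: int = 0) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass of equal length.

    Zero-phase application is used because event *timing* feeds every
    downstream parameter; a causal filter would delay all events by the
    group delay.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[axis] < 3 * (spec.order + 1):
        raise DataError(
            f"series too short ({series.shape[axis]} samples) for order "
            f"{spec.order} zero-phase filtering"
        )
    if not np.isfinite(series).all():
        idx = int(np.argwhere(~np.isfinite(series))[0][0])
        raise DataError(f"non-finite sample at index {idx}")
    b, a = butter(spec.order, spec.cutoff_hz, fs=spec.sampling_rate_hz, btype="low")
    return filtfilt(b, a, series, axis=axis)


def _refine_peaks(y: np.ndarray, idx: np.ndarray, fs: float) -> np.ndarray:
    """Sub-sample peak times by parabolic interpolation around each sample."""
    pos = idx.astype(float)
    ok = (idx > 0) & (idx < len(y) - 1)
    a, b, g = y[idx[ok] - 1], y[idx[ok]], y[idx[ok] + 1]
    denom = a - 2.0 * b + g
    p = np.where(denom != 0.0, 0.5 * (a - g) / np.where(denom == 0.0, 1.0, denom), 0.0)
    pos[ok] = idx[ok] + np.clip(p, -0.5, 0.5)
    return pos / fs


def _find_side_peaks(y: np.ndarray, threshold: float, distance: int):
    """Indices of strict local maxima with value > threshold.

    Plateaus resolve to their left edge (earlier index); edge samples are
    never peaks.
    """
    idx, props = find_peaks(y, height=threshold, distance=distance, plateau_size=(1, None))
    left = props.get("left_edges")
    if left is not None:
        idx = np.asarray(left)
    return idx[y[idx] > threshold]


def detect_gait_events(
    foot_sagittal_gyro: np.ndarray,
    sampling_rate_hz: float,
    side: str = "L",
    threshold_dps: float = 50.0,
    min_separation_s: float = 0.25,
) -> list[GaitEvent]:
    """Detect heel strikes and toe-offs from filtered foot angular velocity.

    Positive peaks strictly above ``threshold_dps`` are heel strikes,
    negative peaks strictly below the negated threshold are toe-offs; at
    most one event of each type per ``min_separation_s`` window, and
    alternation is enforced by discarding the lower-magnitude peak of any
    same-type adjacent pair.  Peak times are refined to sub-sample accuracy
    by parabolic interpolation; the reported peak value is the sample value.
    """
    y = np.asarray(foot_sagittal_gyro, dtype=float)
    if y.size == 0:
        raise DataError("empty signal")
    if threshold_dps <= 0:
        raise ValueError("threshold must be positive")
    distance = max(1, int(round(min_separation_s * sampling_rate_hz)))

    events: list[GaitEvent] = []
    for kind, sign in (("heel_strike", 1.0), ("toe_off", -1.0)):
        idx = _find_side_peaks(sign * y, threshold_dps, distance)
        times = _refine_peaks(sign * y, np.asarray(idx, dtype=int), sampling_rate_hz)
        events.extend(
            GaitEvent(time_s=float(ts), side=side, kind=kind, peak_dps=float(y[i]))
            for ts, i in zip(times, idx)
        )
    events.sort(key=lambda e: e.time_s)
    return _enforce_alternation(events)


def _enforce_alternation(events: list[GaitEvent]) -> list[GaitEvent]:
    """Drop the weaker of any same-type adjacent pair until types alternate."""
    changed = True
    while changed:
        changed = False
        out: list[GaitEvent] = []
        i = 0
        while i < len(events):
            if (
                i + 1 < len(events)
                and events[i].kind == events[i + 1].kind
            ):
                keep = max(events[i], events[i + 1], key=lambda e: abs(e.peak_dps))
                out.append(keep)
                i += 2
                changed = True
            else:
                out.append(events[i])
                i += 1
        events = out
    return events


def segment_cycles(
    events_left: list[GaitEvent], events_right: list[GaitEvent]
) -> dict[str, list[GaitCycle]]:
    """Assemble per-side gait cycles from detected events.

    One cycle per consecutive same-side heel-strike pair containing exactly
    one intervening same-side toe-off; incomplete leading/trailing fragments
    are discarded.  Contralateral toe-off and heel strike falling inside the
    cycle window are attached when present.
    """
    by_side = {"L": events_left, "R": events_right}
    cycles: dict[str, list[GaitCycle]] = {"L": [], "R": []}
    for side, events in by_side.items():
        contra = by_side["R" if side == "L" else "L"]
        hs = [e for e in events if e.kind == "heel_strike"]
        to = [e for e in events if e.kind == "toe_off"]
        if len(hs) < 2:
            continue
        for a, b in zip(hs[:-1], hs[1:]):
            inner = [e for e in to if a.time_s < e.time_s < b.time_s]
            if len(inner) != 1:
                continue
            c_to = [
                e for e in contra
                if e.kind == "toe_off" and a.time_s < e.time_s < b.time_s
            ]
            c_hs = [
                e for e in contra
                if e.kind == "heel_strike" and a.time_s < e.time_s < b.time_s
            ]
            cycles[side].append(
                GaitCycle(
                    side=side,
                    start_hs=a.time_s,
                    toe_off=inner[0].time_s,
                    end_hs=b.time_s,
                    contra_toe_off=c_to[0].time_s if c_to else None,
                    contra_heel_strike=c_hs[0].time_s if c_hs else None,
                )
            )
    return cycles
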