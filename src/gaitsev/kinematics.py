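"""Sagittal-plane kinematics: sensor fusion, joint angles, range of motion.

Segment orientations are estimated with a first-order complementary filter
fusing the integrated sagittal gyro with the accelerometer gravity
inclination; joint angles are differences between adjacent segment
orientations referenced to a static calibration window; per-cycle range of
motion (max minus min within each gait cycle) summarises each joint.

Sign convention: flexion positive for hip and knee, dorsiflexion positive
for the ankle, fixed everywhere.  Only the sagittal plane is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .config import ConfigError
from .signal_prep import DataError, GaitCycle

__all__ = [
    "OrientationSeries",
    "JointAngleSummary",
    "complementary_filter",
    "joint_angles",
    "rom_per_cycle",
    "step_lengths_per_cycle",
    "estimate_step_length",
]


@dataclass
class OrientationSeries:
    """Sagittal orientation estimate for one body segment."""

    segment: str
    time_s: np.ndarray
    angle_deg: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        if len(self.time_s) != len(self.angle_deg):
            raise ValueError("time and angle series must have equal length")


@dataclass
class JointAngleSummary:
    """Per-cycle extrema and ROM for one joint/side."""

    joint: str
    side: str
    max_flexion_deg: np.ndarray  # per cycle
    max_extension_deg: np.ndarray  # per cycle (signed minimum)
    rom_deg: np.ndarray  # per cycle
    skipped_cycles: int = 0

    @property
    def mean_rom_deg(self) -> float:
        return float(np.mean(self.rom_deg)) if self.rom_deg.size else float("nan")


def accel_inclination_deg(accel: np.ndarray) -> np.ndarray:
    """Gravity inclination angle (deg) from a 3-axis accelerometer trace."""
    a = np.asarray(accel, dtype=float)
    return np.degrees(np.arctan2(a[:, 0], a[:, 2]))


def complementary_filter(
    gyro_sagittal_dps: np.ndarray,
    accel_mps2: np.ndarray,
    sampling_rate_hz: float,
    alpha: float = 0.98,
    segment: str = "",
    init_window_s: tuple[float, float] = (0.25, 1.75),
) -> OrientationSeries:
    """Fuse gyro and accelerometer into a sagittal orientation estimate.

    theta_t = alpha * (theta_{t-1} + trapezoidal gyro increment)
              + (1 - alpha) * theta_accel_t

    with theta_0 the mean accelerometer inclination over ``init_window_s``.
    alpha = 1 reduces to pure (trapezoidal) gyro integration, alpha = 0 to
    the per-sample accelerometer inclination.  Samples with zero
    accelerometer norm contribute a pure-integration step.
    """
    omega = np.asarray(gyro_sagittal_dps, dtype=float)
    accel = np.asarray(accel_mps2, dtype=float)
    if omega.ndim != 1 or accel.shape != (omega.size, 3):
        raise DataError("gyro must be 1-D and accel (n, 3) of equal length")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    n = omega.size
    dt = 1.0 / sampling_rate_hz
    t = np.arange(n) * dt

    norms = np.linalg.norm(accel, axis=1)
    theta_acc = np.zeros(n)
    ok = norms > 0
    theta_acc[ok] = np.degrees(np.arctan2(accel[ok, 0], accel[ok, 2]))

    w = (t >= init_window_s[0]) & (t <= init_window_s[1]) & ok
    theta0 = float(theta_acc[w].mean()) if w.any() else float(theta_acc[ok][0]) if ok.any() else 0.0

    incr = np.empty(n)
    incr[0] = 0.0
    incr[1:] = 0.5 * (omega[1:] + omega[:-1]) * dt

    if ok.all():
        u = alpha * incr[1:] + (1.0 - alpha) * theta_acc[1:]
        out, _ = lfilter([1.0], [1.0, -alpha], u, zi=np.array([alpha * theta0]))
        theta = np.concatenate(([theta0], out))
    else:  # rare degenerate samples: explicit recursion with skip steps
        theta = np.empty(n)
        theta[0] = theta0
        for i in range(1, n):
            pred = theta[i - 1] + incr[i]
            theta[i] = alpha * pred + (1.0 - alpha) * theta_acc[i] if ok[i] else pred
    return OrientationSeries(segment=segment, time_s=t, angle_deg=theta, alpha=alpha)


#: joint -> (proximal segment, distal segment) stem names
JOINT_SEGMENTS = {"hip": ("pelvis", "thigh"), "knee": ("thigh", "shank"), "ankle": ("shank", "foot")}


def joint_angles(
    proximal: OrientationSeries,
    distal: OrientationSeries,
    calibration_window_s: tuple[float, float] = (0.25, 1.75),
) -> np.ndarray:
    """Joint angle series: proximal minus distal, re-referenced to standing.

    The mean orientation difference over the static calibration window
    defines the anatomical zero.
    """
    lo, hi = calibration_window_s
    if hi - lo < 0.5:
        raise ConfigError("calibration window must span at least 0.5 s")
    if len(proximal.angle_deg) != len(distal.angle_deg):
        raise DataError("proximal and distal series must share a time base")
    diff = proximal.angle_deg - distal.angle_deg
    w = (proximal.time_s >= lo) & (proximal.time_s <= hi)
    if not w.any():
        raise ConfigError("calibration window outside the recorded time range")
    return diff - diff[w].mean()


def rom_per_cycle(
    time_s: np.ndarray,
    angle_deg: np.ndarray,
    cycles: list[GaitCycle],
    joint: str = "",
    side: str = "",
) -> JointAngleSummary:
    """Per-cycle max, min and range of the joint angle within [start, end)."""
    mx, mn = [], []
    skipped = 0
    t_end = time_s[-1] if len(time_s) else 0.0
    for c in cycles:
        i0 = int(np.searchsorted(time_s, c.start_hs, side="left"))
        i1 = int(np.searchsorted(time_s, c.end_hs, side="left"))  # [start, end)
        if i1 <= i0 or c.end_hs > t_end + 1e-9:
            skipped += 1
            continue
        seg = angle_deg[i0:i1]
        mx.append(float(seg.max()))
        mn.append(float(seg.min()))
    mx_a, mn_a = np.asarray(mx), np.asarray(mn)
    return JointAngleSummary(
        joint=joint,
        side=side,
        max_flexion_deg=mx_a,
        max_extension_deg=mn_a,
        rom_deg=mx_a - mn_a,
        skipped_cycles=skipped,
    )


def step_lengths_per_cycle(
    time_s: np.ndarray,
    shank_angle_deg: np.ndarray,
    cycles: list[GaitCycle],
    leg_length_m: float,
) -> np.ndarray:
    """Pendulum step-length estimates, one per gait cycle.

    step_length = 2 * leg_length * sin(sweep / 2), with sweep the sagittal
    shank excursion (max - min, radians) over the cycle.
    """
    if leg_length_m <= 0:
        raise ValueError("leg length must be positive")
    sweeps = rom_per_cycle(time_s, shank_angle_deg, cycles).rom_deg
    sweeps_rad = np.radians(sweeps)
    if (sweeps_rad >= math.pi).any():
        raise DataError("non-physical shank sweep >= pi rad")
    return 2.0 * leg_length_m * np.sin(sweeps_rad / 2.0)


def estimate_step_length(
    time_s: np.ndarray,
    shank_angle_deg: np.ndarray,
    cycles: list[GaitCycle],
    leg_length_m: float,
) -> float:
    """Mean pendulum step length over the given cycles (m)."""
    per_cycle = step_lengths_per_cycle(time_s, shank_angle_deg, cycles, leg_length_m)
    return float(per_cycle.mean()) if per_cycle.size else float("nan")
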