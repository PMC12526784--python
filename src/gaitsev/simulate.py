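"""Synthesis of multi-segment IMU gait recordings.

Each subject's recording contains ``n_trials`` walks along the walkway, all
sampled at the configured rate, each beginning with a static standing
(calibration) window followed by a smooth walk-up ramp and steady gait.
Seven sensor locations are emulated: pelvis, both thighs, both shanks and
both feet, each with a 3-axis gyroscope (deg/s) and accelerometer (m/s^2).

The sagittal-plane segment angles follow the closed-form per-subject design
of :mod:`gaitsev.waveform`; angular velocities are their analytic time
derivatives and accelerometer channels are the gravity projection of the
segment angle, so that gyroscope integration, accelerometer inclination and
the true angle are mutually consistent.  Heel-strike and toe-off ground
truth is recorded per trial; the foot gyro carries a positive Gaussian pulse
at each heel strike and a negative one at each toe-off, in the configured
80-150 deg/s amplitude band, which is what the downstream +/-50 deg/s
peak-detection rule keys on.

Axis conventions (fixed and relied on by the extraction pipeline):
``SAGITTAL_GYRO_AXIS = 1`` (the y gyro component is the sagittal angular
velocity) and the accelerometer inclination is ``atan2(a_x, a_z)``.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .cohort import SubjectProfile
from .config import CohortConfig
from .waveform import (
    FootSolution,
    shank_phase_rad,
    smoothstep,
    smoothstep_deriv,
    solve_foot,
    solve_knee_phase,
)

__all__ = [
    "SEGMENTS",
    "SAGITTAL_GYRO_AXIS",
    "GRAVITY_MPS2",
    "TrialTrace",
    "ImuRecording",
    "SimulationError",
    "synthesize_recording",
    "simulate_cohort",
]

SEGMENTS = ("pelvis", "thigh_L", "thigh_R", "shank_L", "shank_R", "foot_L", "foot_R")
SAGITTAL_GYRO_AXIS = 1
GRAVITY_MPS2 = 9.80665


class SimulationError(RuntimeError):
    """Raised when a profile cannot be realized on the configured walkway."""


@dataclass
class TrialTrace:
    """One walking trial: per-segment 6-axis series on a common time base."""

    time_s: np.ndarray
    gyro_dps: dict[str, np.ndarray]  # segment -> (n, 3)
    accel_mps2: dict[str, np.ndarray]  # segment -> (n, 3)

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class ImuRecording:
    """All trials of one subject plus per-trial ground-truth gait events."""

    subject_id: str
    sampling_rate_hz: float
    trials: list[TrialTrace]
    #: per trial: list of (time_s, side "L"/"R", "heel_strike"/"toe_off")
    ground_truth_events: list[list[tuple[float, str, str]]]
    n_strides_per_trial: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass
class _SubjectWaveform:
    """Deterministic per-subject waveform parameters."""

    cycle_s: float
    omega: float  # rad/s
    stance_frac: float
    b_deg: float  # shank sinusoid amplitude (half sweep)
    psi_s: float
    knee_amp_deg: float
    psi_k: float
    foot: FootSolution
    phase_offset_r: float  # right-leg offset as cycle fraction (0.5 + asym)


def _design_subject(profile: SubjectProfile, config: CohortConfig, rng) -> _SubjectWaveform:
    p = profile.true_params
    cycle = p.cycle_time
    omega = 2.0 * math.pi / cycle
    stance_frac = p.stance_pct / 100.0
    from .waveform import pendulum_sweep_deg

    b = pendulum_sweep_deg(p.step_length, profile.leg_length_m) / 2.0
    psi_s = shank_phase_rad(stance_frac)
    foot = solve_foot(
        b,
        p.ankle_rom,
        stance_frac,
        omega,
        config.pulse_amplitude_band_dps,
        config.pulse_sigma_bounds_s,
    )
    psi_k = solve_knee_phase(b, p.knee_rom, p.hip_rom, psi_s)
    asym = rng.normal(0.0, config.noise.phase_asymmetry_sd)
    # keep the contralateral offset physical: both double-support phases must
    # stay positive, which requires 1 - stance < 0.5 + asym < stance
    asym = float(np.clip(asym, 0.52 - stance_frac, stance_frac - 0.52))
    return _SubjectWaveform(
        cycle_s=cycle,
        omega=omega,
        stance_frac=stance_frac,
        b_deg=b,
        psi_s=psi_s,
        knee_amp_deg=p.knee_rom / 2.0,
        psi_k=psi_k,
        foot=foot,
        phase_offset_r=0.5 + asym,
    )


def _event_times(wf: _SubjectWaveform, t0: float, n_strides: int):
    """Ground-truth heel-strike / toe-off times for both feet."""
    T, s, phi = wf.cycle_s, wf.stance_frac, wf.phase_offset_r
    k = np.arange(n_strides + 1)
    hs_l = t0 + k * T
    to_l = t0 + (k + s) * T
    kr = np.arange(n_strides)
    hs_r = t0 + (kr + phi) * T
    to_r = t0 + (k + phi - 1.0 + s) * T
    return hs_l, to_l, hs_r, to_r


def _stair(
    t: np.ndarray,
    rises: np.ndarray,
    falls: np.ndarray,
    height: float,
    sigma: float,
    slope_at=None,
):
    """Smooth staircase: +height CDF step at each rise, -height at each fall.

    ``slope_at`` (callable time -> deg/s^2) gives the slope of the slow
    foot-gyro background at each event; when provided, an antisymmetric
    correction term with slope -m at the event centre is added so the *net*
    foot angular velocity attains its local extremum exactly at the event
    time (otherwise the background slope would shift the detected peak by
    about m * sigma^2 / amplitude).
    """
    angle = np.zeros_like(t)
    rate = np.zeros_like(t)
    peak = height / (sigma * math.sqrt(2.0 * math.pi))
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    half = 6.0 * sigma  # transition support; beyond it the step is flat

    # flat staircase level between transitions (cumulative event signs)
    ev = sorted(
        [(float(e), 1.0) for e in rises] + [(float(e), -1.0) for e in falls]
    )
    times = np.array([e for e, _ in ev])
    levels = np.concatenate([[0.0], np.cumsum([s for _, s in ev]) * height])
    angle += levels[np.searchsorted(times + half, t, side="right")]

    for e, sign in ev:
        i0 = max(0, int((e - half) / dt))
        i1 = min(len(t), int((e + half) / dt) + 2)
        z = (t[i0:i1] - e) / sigma
        g = np.exp(-0.5 * z * z)
        # replace the flat step with the smooth CDF transition locally
        angle[i0:i1] += sign * height * (ndtr(z) - (t[i0:i1] >= e + half))
        rate[i0:i1] += sign * peak * g
        if slope_at is not None:
            m = slope_at(e)
            rate[i0:i1] += -m * (t[i0:i1] - e) * g
            angle[i0:i1] += m * sigma * sigma * g
    return angle, rate


def synthesize_recording(
    profile: SubjectProfile, config: CohortConfig | None = None, seed: int = 0
) -> ImuRecording:
    """Synthesize the IMU recording realizing ``profile.true_params``.

    Deterministic given (profile, config, seed); trials share the same gait
    pattern and differ only in the sensor-noise realization.
    """
    config = config or CohortConfig()
    p = profile.true_params
    if p.step_length >= config.walkway_length_m / 4.0:
        raise SimulationError(
            f"step length {p.step_length:.2f} m leaves fewer than 2 strides "
            f"on the {config.walkway_length_m} m walkway"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [int(seed) & 0x7FFFFFFF, zlib.crc32(profile.subject_id.encode()), 1]
        )
    )
    wf = _design_subject(profile, config, rng)

    n_strides = max(2, int(config.walkway_length_m // (2.0 * p.step_length)))
    fs = config.sampling_rate_hz
    t_static = config.static_duration_s
    t0 = t_static + config.ramp_duration_s
    duration = t0 + (n_strides + wf.stance_frac) * wf.cycle_s + 0.4 + 4 * wf.foot.sigma_s
    n = int(math.ceil(duration * fs))
    t = np.arange(n) / fs

    hs_l, to_l, hs_r, to_r = _event_times(wf, t0, n_strides)
    events: list[tuple[float, str, str]] = sorted(
        [(float(e), "L", "heel_strike") for e in hs_l]
        + [(float(e), "L", "toe_off") for e in to_l]
        + [(float(e), "R", "heel_strike") for e in hs_r]
        + [(float(e), "R", "toe_off") for e in to_r]
    )

    env = smoothstep((t - t_static) / config.ramp_duration_s)
    denv = smoothstep_deriv((t - t_static) / config.ramp_duration_s) / config.ramp_duration_s

    angles: dict[str, np.ndarray] = {}
    rates: dict[str, np.ndarray] = {}

    def harmonic(amp: float, chi: np.ndarray, psi: float):
        """(angle, rate) of env-modulated amp * sin(chi - psi)."""
        s_ = amp * np.sin(chi - psi)
        return env * s_, denv * s_ + env * amp * wf.omega * np.cos(chi - psi)

    for side, phase_frac, hs, to in (
        ("L", 0.0, hs_l, to_l),
        ("R", wf.phase_offset_r, hs_r, to_r),
    ):
        chi = wf.omega * (t - t0) - 2.0 * math.pi * phase_frac
        shank_a, shank_r = harmonic(wf.b_deg, chi, wf.psi_s)
        knee_a, knee_r = harmonic(wf.knee_amp_deg, chi, wf.psi_k)
        w1_a, w1_r = harmonic(wf.foot.w1_deg, chi, wf.psi_s)

        def bg_slope(e, _pf=phase_frac):
            """d/dt of the shaping-sinusoid angular rate at an event time."""
            chi_e = wf.omega * (e - t0) - 2.0 * math.pi * _pf
            return -wf.foot.w1_deg * wf.omega**2 * math.sin(chi_e - wf.psi_s)

        stair_a, stair_r = _stair(
            t, hs, to, wf.foot.stair_deg, wf.foot.sigma_s, slope_at=bg_slope
        )
        angles[f"shank_{side}"] = shank_a
        rates[f"shank_{side}"] = shank_r
        angles[f"thigh_{side}"] = shank_a + knee_a
        rates[f"thigh_{side}"] = shank_r + knee_r
        angles[f"foot_{side}"] = stair_a + w1_a
        rates[f"foot_{side}"] = stair_r + w1_r
    angles["pelvis"] = np.zeros(n)
    rates["pelvis"] = np.zeros(n)

    # noise-free sensor baselines, shared by all trials
    base_gyro: dict[str, np.ndarray] = {}
    base_accel: dict[str, np.ndarray] = {}
    for seg in SEGMENTS:
        g = np.zeros((n, 3))
        g[:, SAGITTAL_GYRO_AXIS] = rates[seg]
        th = np.radians(angles[seg])
        a = np.zeros((n, 3))
        a[:, 0] = GRAVITY_MPS2 * np.sin(th)
        a[:, 2] = GRAVITY_MPS2 * np.cos(th)
        base_gyro[seg] = g
        base_accel[seg] = a

    trials: list[TrialTrace] = []
    g_sd = config.noise.gyro_sd_dps
    a_sd = config.noise.accel_sd_mps2
    for _ in range(config.n_trials):
        gn = rng.standard_normal((len(SEGMENTS), n, 3)) * g_sd if g_sd else None
        an = rng.standard_normal((len(SEGMENTS), n, 3)) * a_sd if a_sd else None
        gyro = {}
        accel = {}
        for i, seg in enumerate(SEGMENTS):
            gyro[seg] = base_gyro[seg] + gn[i] if gn is not None else base_gyro[seg]
            accel[seg] = base_accel[seg] + an[i] if an is not None else base_accel[seg]
        trials.append(TrialTrace(time_s=t, gyro_dps=gyro, accel_mps2=accel))

    warn = list(profile.warnings)
    if wf.foot.residual_deg > 0.5:
        warn.append(f"ankle waveform residual {wf.foot.residual_deg:.2f} deg")
    return ImuRecording(
        subject_id=profile.subject_id,
        sampling_rate_hz=fs,
        trials=trials,
        ground_truth_events=[list(events) for _ in range(config.n_trials)],
        n_strides_per_trial=n_strides,
        warnings=warn,
    )


def simulate_cohort(config: CohortConfig | None = None, seed: int | None = None):
    """Yield (profile, recording) pairs for the configured cohort."""
    from .cohort import sample_cohort

    config = config or CohortConfig()
    master = config.seed if seed is None else seed
    for profile in sample_cohort(config, master):
        yield profile, synthesize_recording(profile, config, master)
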