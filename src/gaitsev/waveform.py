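"""Closed-form sagittal waveform design for the gait simulator.

The simulator builds each subject's segment-angle curves from first-harmonic
sinusoids of the gait phase chi = 2*pi*t/T plus a smooth "staircase" on the
foot whose time derivative is exactly the pair of Gaussian gyro pulses that
the event detector looks for (a positive peak at heel strike, a negative
peak at toe-off).  The design is solved per subject so that the extraction
pipeline inverts it exactly in the noiseless limit:

* shank angle   = B * sin(chi - psi_s)          with 2B = pendulum sweep
                                                 needed for the step length
* knee angle    = (K/2) * sin(chi - psi_k)       per-cycle ROM = K
* hip angle     = -(thigh curve), pelvis flat    per-cycle ROM = H
* foot angle    = staircase + w1 * sin(chi - psi_s)
* ankle angle   = shank - foot
                = (B - w1) * sin(chi - psi_s) - staircase

psi_s places the shank maximum at mid-stance and the minimum at mid-swing,
which keeps the extrema of the ankle curve away from the staircase
transitions; the staircase step height dA and the shaping amplitude w1 are
then solved in closed form so the per-cycle ankle range equals the target
ROM.  The hip target fixes psi_k through the resultant-amplitude identity
for the sum of two first harmonics.

Angles are in degrees throughout; phases in radians unless suffixed _deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Cap on the slow foot-gyro background |w1 * omega| (deg/s).  Kept well
#: below the 50 deg/s event threshold so that, with sensor noise on top, no
#: spurious super-threshold peaks appear between gait events.
FOOT_SLOPE_CAP_DPS = 38.0

SQRT_2PI = math.sqrt(2.0 * math.pi)


def stair_height_band(
    amplitude_band_dps: tuple[float, float], sigma_bounds_s: tuple[float, float]
) -> tuple[float, float]:
    """Feasible staircase step height (deg) for a Gaussian gyro pulse.

    A pulse of peak amplitude A (deg/s) and width sigma (s) integrates to a
    step of A * sigma * sqrt(2*pi) degrees.
    """
    a_lo, a_hi = amplitude_band_dps
    s_lo, s_hi = sigma_bounds_s
    return a_lo * s_lo * SQRT_2PI, a_hi * s_hi * SQRT_2PI


def shank_phase_rad(stance_frac: float) -> float:
    """Shank sinusoid phase putting its max at mid-stance, min at mid-swing."""
    return math.pi * stance_frac - math.pi / 2.0


def _edge_cos(stance_frac: float) -> float:
    """Value factor of sin(chi - psi_s) at the heel-strike edge chi = 0."""
    # sin(-psi_s) = cos(pi * stance_frac); negative for stance > 50 %.
    return math.cos(math.pi * stance_frac)


#: Minimum magnitude (deg/s) the net foot-gyro peak must reach at an event:
#: the 50 deg/s detection threshold plus headroom for filtering, sampling
#: off-grid and sensor noise.
EVENT_PEAK_MARGIN_DPS = 62.0


def _w1_range(
    dA: float,
    omega: float,
    stance_frac: float,
    amplitude_band_dps: tuple[float, float],
    sigma_bounds_s: tuple[float, float],
) -> tuple[float, float, float, float]:
    """Admissible (w1_lo, w1_hi) plus (sigma, amplitude) for a stair height.

    The foot shaping sinusoid shares the shank phase, so its angular-rate
    background at the event times is w1 * omega * sin(pi * stance); negative
    w1 eats into the pulse peaks, so it is capped by the detectability
    margin, while positive w1 is capped only by the slow-background slope
    limit.
    """
    sp = math.sin(math.pi * stance_frac)
    sigma = max(sigma_bounds_s[0], dA / (amplitude_band_dps[1] * SQRT_2PI))
    amplitude = dA / (sigma * SQRT_2PI)
    w_slope = FOOT_SLOPE_CAP_DPS / omega
    headroom = max(0.0, amplitude - EVENT_PEAK_MARGIN_DPS)
    w_neg = min(w_slope, headroom / (omega * sp)) if sp > 0 else w_slope
    return -w_neg, w_slope, sigma, amplitude


def _stair_grid(delta_band_deg: tuple[float, float], n: int = 81) -> np.ndarray:
    return np.linspace(delta_band_deg[0], delta_band_deg[1], n)


def ankle_rom_bounds(
    b_deg: float,
    stance_frac: float,
    omega: float,
    delta_band_deg: tuple[float, float],
    amplitude_band_dps: tuple[float, float] = (80.0, 150.0),
    sigma_bounds_s: tuple[float, float] = (0.03, 0.05),
) -> tuple[float, float]:
    """Achievable per-cycle ankle ROM band for a given shank amplitude.

    ``b_deg`` is the shank sinusoid amplitude (half the pendulum sweep),
    ``omega`` the stride angular frequency 2*pi/T in rad/s.  The band is
    restricted to designs whose ankle extrema sit at mid-stance and
    mid-swing ("primary regime", stair height dA <= (1 + ce) * B' with
    B' = B - w1 and ce = cos(pi * stance)), so the realized per-cycle ROM
    is exactly 2*B' - dA, and to designs whose event pulses stay detectable.
    """
    ce = _edge_cos(stance_frac)
    lo, hi = math.inf, -math.inf
    for dA in _stair_grid(delta_band_deg):
        w_lo, w_hi, _, _ = _w1_range(dA, omega, stance_frac, amplitude_band_dps, sigma_bounds_s)
        b_min = max(b_deg - w_hi, dA / (1.0 + ce), 0.25)
        b_max = b_deg - w_lo
        if b_min > b_max:
            continue
        lo = min(lo, 2.0 * b_min - dA)
        hi = max(hi, 2.0 * b_max - dA)
    if not math.isfinite(lo):  # no feasible stair at all (degenerate gait)
        return 1.0, 2.0 * b_deg
    return max(lo, 1.0), hi


@dataclass
class FootSolution:
    """Per-subject foot/ankle waveform parameters."""

    w1_deg: float  #: foot shaping sinusoid amplitude
    stair_deg: float  #: staircase step height dA
    sigma_s: float  #: Gaussian pulse width
    amplitude_dps: float  #: Gaussian pulse peak amplitude
    residual_deg: float  #: |realized - target| ankle ROM left after clamping


def solve_foot(
    b_deg: float,
    ankle_rom_deg: float,
    stance_frac: float,
    omega: float,
    amplitude_band_dps: tuple[float, float] = (80.0, 150.0),
    sigma_bounds_s: tuple[float, float] = (0.03, 0.05),
) -> FootSolution:
    """Solve staircase height and shaping amplitude for the ankle ROM target.

    In the primary regime (stair height below (1 + ce) * B'), the ankle curve
    attains its max at mid-stance and its min at mid-swing, so the per-cycle
    range is exactly 2*B' - dA with B' = B - w1.  The solver stays in that
    regime, which keeps the extrema away from the staircase transitions and
    makes the realized ROM analytic.
    """
    a = ankle_rom_deg
    ce = _edge_cos(stance_frac)

    # Scan the admissible stair heights; for each, B' = (a + dA) / 2 realizes
    # the target exactly (ROM = 2*B' - dA in the primary regime).  Feasible
    # candidates need w1 = B - B' inside the detectability/slope range and
    # the regime condition dA <= (1 + ce) * B'; prefer the smallest |w1|.
    best: tuple[float, FootSolution] | None = None
    fallback: tuple[float, FootSolution] | None = None
    for dA in _stair_grid(stair_height_band(amplitude_band_dps, sigma_bounds_s)):
        w_lo, w_hi, sigma, amplitude = _w1_range(
            dA, omega, stance_frac, amplitude_band_dps, sigma_bounds_s
        )
        b_eff = (a + dA) / 2.0
        w1 = b_deg - b_eff
        violation = max(
            0.0, w_lo - w1, w1 - w_hi, (dA - (1.0 + ce) * b_eff) / (1.0 + ce)
        )
        w1_c = float(np.clip(w1, w_lo, w_hi))
        realized = 2.0 * (b_deg - w1_c) - dA
        sol = FootSolution(w1_c, dA, sigma, amplitude, abs(realized - a))
        if violation == 0.0:
            if best is None or abs(w1) < best[0]:
                best = (abs(w1), sol)
        elif fallback is None or violation < fallback[0]:
            fallback = (violation, sol)
    return best[1] if best is not None else fallback[1]  # type: ignore[index]


def solve_knee_phase(
    b_deg: float, knee_rom_deg: float, hip_rom_deg: float, psi_s: float
) -> float:
    """Phase of the knee sinusoid realizing the hip ROM target.

    thigh = shank + knee_curve, pelvis = 0, hip = -thigh.  The hip per-cycle
    range is twice the resultant amplitude E of the two first harmonics:

        E^2 = B^2 + (K/2)^2 + 2 * B * (K/2) * cos(psi_k - psi_s)

    and the solver inverts this for psi_k given E = hip ROM / 2.
    """
    k2 = knee_rom_deg / 2.0
    e = hip_rom_deg / 2.0
    denom = 2.0 * b_deg * k2
    if denom <= 0:
        return psi_s + math.pi / 2.0
    c = (e * e - b_deg * b_deg - k2 * k2) / denom
    c = float(np.clip(c, -1.0, 1.0))
    return psi_s + math.acos(c)


def hip_feasible_band(b_deg: float, knee_rom_deg: float) -> tuple[float, float]:
    """Hip ROM band reachable for a given shank amplitude and knee ROM."""
    k2 = knee_rom_deg / 2.0
    return 2.0 * (abs(b_deg - k2) + 0.5), 2.0 * (b_deg + k2 - 0.5)


def pendulum_sweep_deg(step_length_m: float, leg_length_m: float) -> float:
    """Shank sweep angle (deg) inverting the pendulum step-length model."""
    ratio = step_length_m / (2.0 * leg_length_m)
    if not 0.0 <= ratio < 1.0:
        raise ValueError(
            f"step length {step_length_m!r} incompatible with leg length "
            f"{leg_length_m!r} (ratio {ratio:.3f} outside [0, 1))"
        )
    return math.degrees(2.0 * math.asin(ratio))


def smoothstep(x: np.ndarray) -> np.ndarray:
    """C1 ramp 0 -> 1 on [0, 1] (clamped outside)."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def smoothstep_deriv(x: np.ndarray) -> np.ndarray:
    inside = (x > 0.0) & (x < 1.0)
    x = np.clip(x, 0.0, 1.0)
    return np.where(inside, 6.0 * x * (1.0 - x), 0.0)
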