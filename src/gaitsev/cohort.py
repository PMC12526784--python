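"""Synthetic four-group cohort sampling.

Draws demographics and ground-truth gait parameters for a cohort of healthy
controls and people with MCI, mild, and moderate dementia, calibrated to the
group-conditional summary statistics of the study tables.  Internal
consistency of the parameter set is enforced by construction: cadence is the
primary temporal draw (cycle time and step time are derived from it),
velocity is drawn and step length derived, and the double-support phases
follow from the stance percentage and the contralateral phase offset.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .config import GROUP_CDR, GROUPS, CohortConfig, Dist
from .waveform import (
    ankle_rom_bounds,
    hip_feasible_band,
    pendulum_sweep_deg,
    stair_height_band,
)

__all__ = [
    "GroupLabel",
    "GaitParameterSet",
    "SubjectProfile",
    "sample_cohort",
    "subject_rng",
]


@dataclass(frozen=True)
class GroupLabel:
    """Severity group with its Clinical Dementia Rating (CDR)."""

    value: str

    def __post_init__(self) -> None:
        if self.value not in GROUPS:
            raise ValueError(f"unknown group {self.value!r}")

    @property
    def cdr(self) -> float:
        return GROUP_CDR[self.value]

    @classmethod
    def from_cdr(cls, cdr: float) -> "GroupLabel":
        for g, c in GROUP_CDR.items():
            if c == cdr:
                return cls(g)
        raise ValueError(f"no group with CDR {cdr!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class GaitParameterSet:
    """Ground-truth spatiotemporal and kinematic gait parameters.

    Units: cadence steps/min, times s, lengths m, velocity m/s, phase
    percentages % of gait cycle, ROMs degrees (sagittal plane).
    """

    cadence: float
    cycle_time: float
    step_time: float
    step_length: float
    velocity: float
    stance_pct: float
    swing_pct: float
    initial_double_support_pct: float
    single_support_pct: float
    terminal_double_support_pct: float
    hip_rom: float
    knee_rom: float
    ankle_rom: float

    FIELDS = (
        "cadence",
        "cycle_time",
        "step_time",
        "step_length",
        "velocity",
        "stance_pct",
        "swing_pct",
        "initial_double_support_pct",
        "single_support_pct",
        "terminal_double_support_pct",
        "hip_rom",
        "knee_rom",
        "ankle_rom",
    )

    def __post_init__(self) -> None:
        if abs(self.stance_pct + self.swing_pct - 100.0) > 1e-9:
            raise ValueError("stance_pct + swing_pct must equal 100")
        if abs(self.cycle_time - 120.0 / self.cadence) > 1e-9:
            raise ValueError("cycle_time must equal 120 / cadence")
        if abs(self.step_time - 60.0 / self.cadence) > 1e-9:
            raise ValueError("step_time must equal 60 / cadence")
        if abs(self.velocity - self.step_length / self.step_time) > 1e-9:
            raise ValueError("velocity must equal step_length / step_time")
        ds_sum = (
            self.initial_double_support_pct
            + self.single_support_pct
            + self.terminal_double_support_pct
        )
        if abs(ds_sum - self.stance_pct) > 0.5:
            raise ValueError("support phases must sum to the stance percentage")
        for rom in (self.hip_rom, self.knee_rom, self.ankle_rom):
            if rom <= 0:
                raise ValueError("joint ROMs must be positive")

    @classmethod
    def from_primary(
        cls,
        cadence: float,
        velocity: float,
        stance_pct: float,
        hip_rom: float,
        knee_rom: float,
        ankle_rom: float,
    ) -> "GaitParameterSet":
        """Build a consistent parameter set from the primary draws.

        The double-support split is tied to stance: with a half-cycle
        contralateral offset, both the initial and terminal double-support
        phases equal stance% - 50 and single support equals the contralateral
        swing, 100 - stance%.
        """
        step_time = 60.0 / cadence
        ds = stance_pct - 50.0
        return cls(
            cadence=cadence,
            cycle_time=120.0 / cadence,
            step_time=step_time,
            step_length=velocity * step_time,
            velocity=velocity,
            stance_pct=stance_pct,
            swing_pct=100.0 - stance_pct,
            initial_double_support_pct=ds,
            single_support_pct=100.0 - stance_pct,
            terminal_double_support_pct=ds,
            hip_rom=hip_rom,
            knee_rom=knee_rom,
            ankle_rom=ankle_rom,
        )

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in self.FIELDS}


@dataclass
class SubjectProfile:
    """Demographics, group label and ground-truth gait parameters."""

    subject_id: str
    group: GroupLabel
    age: float
    sex: str
    height_cm: float
    weight_kg: float
    leg_length_m: float
    true_params: GaitParameterSet
    warnings: list[str] = field(default_factory=list)

    @property
    def bmi(self) -> float:
        return self.weight_kg / (self.height_cm / 100.0) ** 2


def subject_rng(master_seed: int, subject_id: str) -> np.random.Generator:
    """Independent, reproducible stream for one subject.

    Derived by stable hashing of (master seed, subject id) so that per-subject
    draws do not depend on cohort composition or iteration order.
    """
    tag = zlib.crc32(subject_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, tag]))


def _draw(rng: np.random.Generator, dist: Dist) -> float:
    value = rng.normal(dist.loc, dist.scale)
    return float(np.clip(value, dist.lo, dist.hi))


_GROUP_PREFIX = {
    "healthy_control": "hc",
    "mci": "mci",
    "mild_dementia": "mild",
    "moderate_dementia": "mod",
}


def sample_cohort(config: CohortConfig | None = None, seed: int | None = None) -> list[SubjectProfile]:
    """Sample the synthetic cohort.

    Returns one :class:`SubjectProfile` per subject, ``sum(group_sizes)`` in
    total, in group order healthy -> MCI -> mild -> moderate.  ``seed``
    overrides ``config.seed``.
    """
    config = config or CohortConfig()
    config.validate()
    master = config.seed if seed is None else seed

    profiles: list[SubjectProfile] = []
    for group in GROUPS:
        n = config.group_sizes.get(group, 0)
        gp = config.group_params[group]
        for i in range(n):
            sid = f"{_GROUP_PREFIX[group]}{i + 1:03d}"
            rng = subject_rng(master, sid)
            profiles.append(_sample_subject(sid, group, gp, config, rng))
    return profiles


def _sample_subject(sid, group, gp, config: CohortConfig, rng) -> SubjectProfile:
    warnings: list[str] = []
    age = _draw(rng, gp.age)
    sex = "male" if rng.random() < gp.sex_male_prop else "female"
    height = _draw(rng, gp.height)
    weight = _draw(rng, gp.weight)
    leg_length = config.leg_length_fraction * height / 100.0

    cadence = _draw(rng, gp.cadence)
    velocity = _draw(rng, gp.velocity)
    stance = _draw(rng, gp.stance_pct)
    hip = _draw(rng, gp.hip_rom)
    knee = _draw(rng, gp.knee_rom)
    ankle = _draw(rng, gp.ankle_rom)

    # Geometric consistency of the step length with the pendulum model and
    # the walkway (the signal waveforms must be able to realize the draw).
    step_time = 60.0 / cadence
    step_length = velocity * step_time
    sl_cap = min(0.98 * config.walkway_length_m / 4.0, 1.9 * leg_length)
    if step_length > sl_cap or step_length < 0.08:
        step_length = float(np.clip(step_length, 0.08, sl_cap))
        velocity = step_length / step_time
        warnings.append("step_length clamped to geometric bounds")

    sweep = pendulum_sweep_deg(step_length, leg_length)
    b = sweep / 2.0
    omega = 2.0 * np.pi * cadence / 120.0

    hip_lo, hip_hi = hip_feasible_band(b, knee)
    if not hip_lo <= hip <= hip_hi:
        hip = float(np.clip(hip, hip_lo, hip_hi))
        warnings.append("hip_rom clamped to waveform-feasible band")

    d_band = stair_height_band(config.pulse_amplitude_band_dps, config.pulse_sigma_bounds_s)
    a_lo, a_hi = ankle_rom_bounds(
        b,
        stance / 100.0,
        omega,
        d_band,
        config.pulse_amplitude_band_dps,
        config.pulse_sigma_bounds_s,
    )
    if not a_lo + 0.25 <= ankle <= a_hi - 0.25:
        ankle = float(np.clip(ankle, a_lo + 0.25, a_hi - 0.25))
        warnings.append("ankle_rom clamped to waveform-feasible band")

    params = GaitParameterSet.from_primary(cadence, velocity, stance, hip, knee, ankle)
    return SubjectProfile(
        subject_id=sid,
        group=GroupLabel(group),
        age=age,
        sex=sex,
        height_cm=height,
        weight_kg=weight,
        leg_length_m=leg_length,
        true_params=params,
        warnings=warnings,
    )


def cohort_counts(profiles: Iterable[SubjectProfile]) -> dict[str, int]:
    counts = {g: 0 for g in GROUPS}
    for p in profiles:
        counts[p.group.value] += 1
    return counts
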