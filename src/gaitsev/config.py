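"""Cohort and pipeline configuration.

All numeric defaults of the study design live here: group sizes of the
four-group cohort (healthy control, MCI, mild dementia, moderate dementia),
trial structure (8 trials along an 8 m walkway at 100 Hz), the per-group
distributions of the gait parameters and demographics used to calibrate the
synthetic cohort, and the signal-processing constants (4th-order Butterworth
at 20 Hz, the +/-50 deg/s gyro event threshold).

Parameters summarised in the source tables as median (Q1-Q3) are modelled as
normals with mean = median and SD = (Q3 - Q1) / 1.349 (the normal-IQR
conversion); parameters summarised as mean +/- SD use those moments directly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

GROUPS = ("healthy_control", "mci", "mild_dementia", "moderate_dementia")

#: Clinical Dementia Rating attached to each group (bijective).
GROUP_CDR = {
    "healthy_control": 0.0,
    "mci": 0.5,
    "mild_dementia": 1.0,
    "moderate_dementia": 2.0,
}

#: Normal-distribution conversion factor: IQR of a normal = 1.349 sigma.
IQR_TO_SD = 1.0 / 1.349


def _sd(q1: float, q3: float) -> float:
    return (q3 - q1) * IQR_TO_SD


@dataclass
class Dist:
    """A univariate normal draw with truncation bounds."""

    loc: float
    scale: float
    lo: float = -float("inf")
    hi: float = float("inf")

    def validate(self, name: str) -> None:
        import math

        for attr in ("loc", "scale"):
            v = getattr(self, attr)
            if not math.isfinite(v):
                raise ConfigError(f"{name}.{attr} must be finite, got {v!r}")
        if self.scale < 0:
            raise ConfigError(f"{name}.scale must be >= 0, got {self.scale!r}")
        if self.loc <= 0:
            raise ConfigError(f"{name}.loc must be positive, got {self.loc!r}")


class ConfigError(ValueError):
    """Raised for invalid cohort / pipeline configuration values."""


@dataclass
class GroupParams:
    """Per-group generative distributions for gait parameters and demographics.

    Units: cadence steps/min, velocity m/s, stance percent of gait cycle,
    joint ROMs degrees, age years, height cm, weight kg.
    """

    cadence: Dist
    velocity: Dist
    stance_pct: Dist
    hip_rom: Dist
    knee_rom: Dist
    ankle_rom: Dist
    age: Dist
    height: Dist
    weight: Dist
    sex_male_prop: float

    def validate(self, group: str) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, Dist):
                v.validate(f"{group}.{f.name}")
        if not 0.0 <= self.sex_male_prop <= 1.0:
            raise ConfigError(f"{group}.sex_male_prop must lie in [0, 1]")


@dataclass
class NoiseConfig:
    """Sensor and gait-pattern noise levels for the simulator.

    The gyro/accel levels are white-noise SDs added per sample before
    filtering; the phase asymmetry is the SD of the per-subject left/right
    contralateral offset (as a fraction of the gait cycle).
    """

    gyro_sd_dps: float = 5.0
    accel_sd_mps2: float = 0.2
    phase_asymmetry_sd: float = 0.01

    def scaled(self, factor: float) -> "NoiseConfig":
        return NoiseConfig(
            self.gyro_sd_dps * factor,
            self.accel_sd_mps2 * factor,
            self.phase_asymmetry_sd * factor,
        )


def default_group_params() -> dict[str, GroupParams]:
    """Group-conditional distributions calibrated to the study's summary tables."""
    return {
        "healthy_control": GroupParams(
            cadence=Dist(110.4, 6.1, 70.0, 145.0),
            velocity=Dist(1.2, _sd(1.2, 1.3), 0.25, 2.0),
            stance_pct=Dist(61.8, _sd(60.8, 62.9), 52.0, 75.0),
            hip_rom=Dist(47.8, _sd(45.0, 51.1), 10.0, 80.0),
            knee_rom=Dist(53.9, _sd(51.5, 56.6), 12.0, 85.0),
            ankle_rom=Dist(32.1, 3.7, 8.0, 60.0),
            age=Dist(74.0, _sd(72.0, 75.0), 60.0, 100.0),
            height=Dist(158.5, _sd(153.0, 165.0), 135.0, 195.0),
            weight=Dist(60.6, 9.8, 35.0, 110.0),
            sex_male_prop=20 / 54,
        ),
        "mci": GroupParams(
            cadence=Dist(99.2, 4.6, 65.0, 135.0),
            velocity=Dist(1.0, _sd(0.9, 1.1), 0.25, 2.0),
            stance_pct=Dist(63.7, _sd(60.9, 65.7), 52.0, 75.0),
            hip_rom=Dist(42.4, _sd(38.1, 44.8), 10.0, 80.0),
            knee_rom=Dist(48.1, _sd(44.6, 54.4), 12.0, 85.0),
            ankle_rom=Dist(23.8, 4.2, 8.0, 60.0),
            age=Dist(75.5, _sd(72.0, 82.0), 60.0, 100.0),
            height=Dist(159.0, _sd(152.0, 165.0), 135.0, 195.0),
            weight=Dist(62.6, 9.8, 35.0, 110.0),
            sex_male_prop=15 / 34,
        ),
        "mild_dementia": GroupParams(
            cadence=Dist(89.8, 7.9, 60.0, 130.0),
            velocity=Dist(0.7, _sd(0.6, 0.8), 0.25, 2.0),
            stance_pct=Dist(60.6, _sd(58.0, 63.9), 52.0, 75.0),
            hip_rom=Dist(33.3, _sd(27.3, 36.7), 10.0, 80.0),
            knee_rom=Dist(39.4, _sd(35.6, 40.3), 12.0, 85.0),
            ankle_rom=Dist(23.9, 5.6, 8.0, 60.0),
            age=Dist(84.0, _sd(77.0, 86.0), 60.0, 100.0),
            height=Dist(150.0, _sd(147.0, 158.0), 135.0, 195.0),
            weight=Dist(54.3, 7.8, 35.0, 110.0),
            sex_male_prop=4 / 25,
        ),
        "moderate_dementia": GroupParams(
            cadence=Dist(83.8, 9.1, 55.0, 125.0),
            velocity=Dist(0.6, _sd(0.4, 0.6), 0.25, 2.0),
            stance_pct=Dist(63.9, _sd(61.4, 67.5), 52.0, 75.0),
            hip_rom=Dist(28.6, _sd(26.0, 35.2), 10.0, 80.0),
            knee_rom=Dist(38.9, _sd(35.4, 39.9), 12.0, 85.0),
            ankle_rom=Dist(23.5, 9.3, 8.0, 60.0),
            age=Dist(86.0, _sd(76.0, 89.0), 60.0, 100.0),
            height=Dist(155.0, _sd(147.0, 170.0), 135.0, 195.0),
            weight=Dist(54.1, 10.8, 35.0, 110.0),
            sex_male_prop=10 / 26,
        ),
    }


@dataclass
class CohortConfig:
    """Full configuration for cohort sampling and IMU signal synthesis."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "healthy_control": 54,
            "mci": 34,
            "mild_dementia": 25,
            "moderate_dementia": 26,
        }
    )
    group_params: dict[str, GroupParams] = field(default_factory=default_group_params)
    n_trials: int = 8
    walkway_length_m: float = 8.0
    sampling_rate_hz: float = 100.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    #: anthropometric leg length as a fraction of standing height
    leg_length_fraction: float = 0.53
    #: duration of the initial static standing (calibration) window, seconds
    static_duration_s: float = 2.0
    #: walk-up ramp between standing and steady gait, seconds
    ramp_duration_s: float = 0.5
    #: gyro event-pulse width (Gaussian SD) bounds, seconds
    pulse_sigma_bounds_s: tuple[float, float] = (0.03, 0.05)
    #: gyro event-pulse amplitude band, deg/s
    pulse_amplitude_band_dps: tuple[float, float] = (80.0, 150.0)
    seed: int = 0

    def validate(self) -> None:
        if not self.group_sizes or all(n == 0 for n in self.group_sizes.values()):
            raise ConfigError("at least one group must be non-empty")
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ConfigError(f"unknown group {g!r}")
            if n < 0:
                raise ConfigError(f"group_sizes[{g!r}] must be >= 0, got {n}")
        for g, gp in self.group_params.items():
            gp.validate(g)
        if self.n_trials < 1:
            raise ConfigError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.walkway_length_m <= 0:
            raise ConfigError("walkway_length_m must be positive")
        if self.sampling_rate_hz <= 0:
            raise ConfigError("sampling_rate_hz must be positive")
        if not 0 < self.leg_length_fraction < 1:
            raise ConfigError("leg_length_fraction must lie in (0, 1)")
        if self.static_duration_s < 2.0:
            raise ConfigError("static_duration_s must be >= 2 s (calibration window)")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["pulse_sigma_bounds_s"] = list(self.pulse_sigma_bounds_s)
        d["pulse_amplitude_band_dps"] = list(self.pulse_amplitude_band_dps)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CohortConfig":
        d = dict(d)
        if "group_params" in d:
            d["group_params"] = {
                g: GroupParams(
                    **{
                        k: (Dist(**v) if isinstance(v, dict) else v)
                        for k, v in gp.items()
                    }
                )
                for g, gp in d["group_params"].items()
            }
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseConfig(**d["noise"])
        for key in ("pulse_sigma_bounds_s", "pulse_amplitude_band_dps"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass
class PipelineConfig:
    """Extraction / analysis stage constants."""

    filter_order: int = 4
    filter_cutoff_hz: float = 20.0
    event_threshold_dps: float = 50.0
    min_separation_s: float = 0.25
    #: complementary-filter fusion coefficient
    alpha: float = 0.98
    #: static window (s) used for orientation init and joint-angle calibration
    calibration_window_s: tuple[float, float] = (0.25, 1.75)
    #: subject-level aggregation of per-cycle values: "mean" or "median"
    aggregate: str = "mean"
    relieff_k: int = 10
    n_features_select: int = 4
    svm_folds: int = 5
    svm_kernel: str = "rbf"

    def validate(self, sampling_rate_hz: float) -> None:
        if self.filter_cutoff_hz >= sampling_rate_hz / 2:
            raise ConfigError("filter cutoff must be below the Nyquist frequency")
        if self.event_threshold_dps <= 0:
            raise ConfigError("event threshold must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError("alpha must lie in [0, 1]")
        if self.aggregate not in ("mean", "median"):
            raise ConfigError("aggregate must be 'mean' or 'median'")


def noiseless(config: CohortConfig | None = None) -> CohortConfig:
    """Copy of *config* (default config if None) with all noise sources zeroed."""
    cfg = config or CohortConfig()
    return dataclasses.replace(cfg, noise=NoiseConfig(0.0, 0.0, 0.0))
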