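"""Simulator contracts: event grids, determinism, and the round-trip with
the extraction pipeline (the module's central inverse-consistency check)."""

import dataclasses

import numpy as np
import pytest

from gaitsev import (
    extract_features,
    noiseless,
    sample_cohort,
    synthesize_recording,
)
from gaitsev.cohort import GaitParameterSet
from gaitsev.simulate import SAGITTAL_GYRO_AXIS, SimulationError
from tests.conftest import assert_relative_close

NAME_MAP = {"gait_cycle_time": "cycle_time"}
ALL_FIELDS = (
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
    "step_time",
    "step_length",
)


def _true(params: GaitParameterSet, feature: str) -> float:
    return getattr(params, NAME_MAP.get(feature, feature))


def test_noiseless_heel_strikes_realize_cycle_time(small_noiseless_cfg):
    """Ground-truth same-side heel strikes are spaced exactly one cycle."""
    profile = sample_cohort(small_noiseless_cfg, seed=2)[0]
    profile.true_params = GaitParameterSet.from_primary(
        cadence=100.0,  # cycle time exactly 1.2 s
        velocity=profile.true_params.velocity,
        stance_pct=profile.true_params.stance_pct,
        hip_rom=profile.true_params.hip_rom,
        knee_rom=profile.true_params.knee_rom,
        ankle_rom=profile.true_params.ankle_rom,
    )
    rec = synthesize_recording(profile, small_noiseless_cfg, seed=2)
    hs = [t for (t, s, k) in rec.ground_truth_events[0] if s == "L" and k == "heel_strike"]
    assert np.allclose(np.diff(hs), 1.2, atol=1e-12)


def test_recording_structure(small_noiseless_cfg):
    profile = sample_cohort(small_noiseless_cfg, seed=2)[0]
    rec = synthesize_recording(profile, small_noiseless_cfg, seed=2)
    assert len(rec.trials) == small_noiseless_cfg.n_trials
    for trial in rec.trials:
        assert set(trial.gyro_dps) == {
            "pelvis", "thigh_L", "thigh_R", "shank_L", "shank_R", "foot_L", "foot_R",
        }
        n = len(trial.time_s)
        assert np.allclose(np.diff(trial.time_s), 0.01)
        for seg in trial.gyro_dps:
            assert trial.gyro_dps[seg].shape == (n, 3)
            assert trial.accel_mps2[seg].shape == (n, 3)
    # >= 2 s static standing before walking: no events before 2 s
    assert min(t for (t, _, _) in rec.ground_truth_events[0]) >= 2.0


def test_event_pulses_in_configured_band(small_noiseless_cfg):
    """Foot-gyro pulses peak inside the configured 80-150 deg/s band."""
    for profile in sample_cohort(small_noiseless_cfg, seed=4)[::5]:
        rec = synthesize_recording(profile, small_noiseless_cfg, seed=4)
        g = rec.trials[0].gyro_dps["foot_L"][:, SAGITTAL_GYRO_AXIS]
        # peak includes the shaping background, so allow its +/-38 deg/s span
        assert 50.0 < g.max() <= 150.0 + 38.0
        assert -150.0 - 38.0 <= g.min() < -50.0


def test_determinism_and_noise_seeds(small_cfg):
    profile = sample_cohort(small_cfg, seed=3)[0]
    a = synthesize_recording(profile, small_cfg, seed=3)
    b = synthesize_recording(profile, small_cfg, seed=3)
    c = synthesize_recording(profile, small_cfg, seed=4)
    ga = a.trials[0].gyro_dps["foot_L"]
    assert np.array_equal(ga, b.trials[0].gyro_dps["foot_L"])
    assert not np.array_equal(ga, c.trials[0].gyro_dps["foot_L"])


def test_too_long_step_raises(small_noiseless_cfg):
    profile = sample_cohort(small_noiseless_cfg, seed=1)[0]
    p = profile.true_params
    profile.true_params = GaitParameterSet.from_primary(
        cadence=p.cadence,
        velocity=2.2 / p.step_time * p.velocity / p.velocity,  # step length 2.2 m
        stance_pct=p.stance_pct,
        hip_rom=p.hip_rom,
        knee_rom=p.knee_rom,
        ankle_rom=p.ankle_rom,
    )
    with pytest.raises(SimulationError, match="step length"):
        synthesize_recording(profile, small_noiseless_cfg, seed=1)


def test_noiseless_round_trip_within_one_percent(small_noiseless_cfg, pipeline_cfg):
    """Central contract: the extraction pipeline inverts the simulator.

    For noiseless recordings every gait parameter (temporal, spatial and
    kinematic) is recovered within 1% relative error.
    """
    for profile in sample_cohort(small_noiseless_cfg, seed=1):
        rec = synthesize_recording(profile, small_noiseless_cfg, seed=1)
        feats = extract_features(rec, profile.leg_length_m, pipeline_cfg)
        assert feats is not None
        for f in ALL_FIELDS:
            assert_relative_close(feats.values[f], _true(profile.true_params, f), 0.01)


def test_noisy_round_trip_within_five_percent(small_cfg, pipeline_cfg):
    """With default sensor noise, >= 95% of subjects recover all parameters
    within 5% relative error."""
    ok = total = 0
    for seed in (1, 2, 3):
        for profile in sample_cohort(small_cfg, seed=seed):
            rec = synthesize_recording(profile, small_cfg, seed=seed)
            feats = extract_features(rec, profile.leg_length_m, pipeline_cfg)
            total += 1
            if feats is not None and all(
                abs(feats.values[f] - _true(profile.true_params, f))
                <= 0.05 * abs(_true(profile.true_params, f))
                for f in ALL_FIELDS
            ):
                ok += 1
    assert ok / total >= 0.95


def test_event_detectability_under_noise(small_cfg, pipeline_cfg):
    """>= 99% of ground-truth events are recovered within +/-20 ms."""
    from gaitsev.signal_prep import FilterSpec, detect_gait_events, lowpass_filter

    spec = FilterSpec(small_cfg.sampling_rate_hz)
    found = total = 0
    for profile in sample_cohort(small_cfg, seed=6):
        rec = synthesize_recording(profile, small_cfg, seed=6)
        for trial, truth in zip(rec.trials[:2], rec.ground_truth_events[:2]):
            for side in ("L", "R"):
                g = lowpass_filter(
                    trial.gyro_dps[f"foot_{side}"][:, SAGITTAL_GYRO_AXIS], spec
                )
                events = detect_gait_events(g, small_cfg.sampling_rate_hz, side=side)
                det = {k: [e.time_s for e in events if e.kind == k] for k in
                       ("heel_strike", "toe_off")}
                for (t, s, kind) in truth:
                    if s != side:
                        continue
                    total += 1
                    if det[kind] and min(abs(d - t) for d in det[kind]) <= 0.020:
                        found += 1
    assert found / total >= 0.99


def test_group_velocity_ordering(small_cfg):
    """Median generative velocity strictly decreases with severity."""
    meds = {g: [] for g in ("healthy_control", "mci", "mild_dementia", "moderate_dementia")}
    for seed in range(10):
        profiles = sample_cohort(small_cfg, seed=seed)
        for g in meds:
            meds[g].append(
                np.median([p.true_params.velocity for p in profiles if p.group.value == g])
            )
    m = {g: np.median(v) for g, v in meds.items()}
    assert m["healthy_control"] > m["mci"] > m["mild_dementia"] > m["moderate_dementia"]


def test_noiseless_config_helper(small_cfg):
    cfg = noiseless(small_cfg)
    assert cfg.noise.gyro_sd_dps == 0
    assert cfg.noise.accel_sd_mps2 == 0
    assert cfg.noise.phase_asymmetry_sd == 0
    assert small_cfg.noise.gyro_sd_dps == 5.0  # original untouched
    assert dataclasses.replace(cfg).group_sizes == small_cfg.group_sizes
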