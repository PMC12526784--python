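"""Shared fixtures: small synthetic cohorts and extracted feature tables."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from gaitsev import (
    CohortConfig,
    PipelineConfig,
    build_feature_table,
    extract_features,
    noiseless,
    sample_cohort,
    synthesize_recording,
)

SMALL_SIZES = {
    "healthy_control": 6,
    "mci": 6,
    "mild_dementia": 6,
    "moderate_dementia": 6,
}


@pytest.fixture(scope="session")
def small_cfg() -> CohortConfig:
    return CohortConfig(group_sizes=dict(SMALL_SIZES))


@pytest.fixture(scope="session")
def small_noiseless_cfg() -> CohortConfig:
    return noiseless(CohortConfig(group_sizes=dict(SMALL_SIZES)))


@pytest.fixture(scope="session")
def pipeline_cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def noiseless_subject(small_noiseless_cfg, pipeline_cfg):
    """One noiseless healthy subject: (profile, recording, features)."""
    profile = sample_cohort(small_noiseless_cfg, seed=1)[0]
    recording = synthesize_recording(profile, small_noiseless_cfg, seed=1)
    feats = extract_features(recording, profile.leg_length_m, pipeline_cfg)
    return profile, recording, feats


@pytest.fixture(scope="session")
def small_table(small_cfg, pipeline_cfg):
    """Feature table extracted from the small default-noise cohort."""
    table, excluded = build_feature_table(small_cfg, pipeline_cfg, seed=7)
    assert not excluded
    return table


def true_param_table(config: CohortConfig, seed: int):
    """Feature table assembled directly from the generative ground truth.

    Used by statistical-power tests where the full-size cohort matters but
    signal synthesis would be wasteful; extraction recovers these values to
    within a fraction of a percent (round-trip tests).
    """
    import pandas as pd

    from gaitsev.features import FEATURE_NAMES

    name_map = {"gait_cycle_time": "cycle_time"}
    rows = []
    for p in sample_cohort(config, seed):
        row = {"subject_id": p.subject_id, "group": p.group.value, "cdr": p.group.cdr}
        for f in FEATURE_NAMES:
            row[f] = getattr(p.true_params, name_map.get(f, f))
        rows.append(row)
    return pd.DataFrame(rows)


def assert_relative_close(actual: float, expected: float, rel: float) -> None:
    assert np.isfinite(actual)
    assert abs(actual - expected) <= rel * abs(expected), (
        f"{actual} vs {expected} (rel {abs(actual - expected) / abs(expected):.4f})"
    )
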