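"""Shared fixtures: small synthetic cohorts and their feature matrices.

Unit tests use a scaled-down cohort (few subjects, 40 s per task) so the
whole suite stays fast; the acceptance tests build their own cohorts at the
sizes they need.
"""

from dataclasses import replace

import numpy as np
import pytest

from elwhar import (
    CohortConfig,
    WindowingConfig,
    build_feature_matrix,
    default_task_profiles,
    segment,
    simulate_cohort,
)


def short_config(n_subjects=5, duration_s=40.0, master_seed=7, **kwargs) -> CohortConfig:
    profiles = [replace(p, duration_s=duration_s) for p in default_task_profiles()]
    return CohortConfig(
        n_subjects=n_subjects, task_profiles=profiles, master_seed=master_seed, **kwargs
    )


@pytest.fixture(scope="session")
def small_cohort():
    """5 subjects, 40 s per task, default heterogeneity."""
    return simulate_cohort(short_config())


@pytest.fixture(scope="session")
def windows10(small_cohort):
    cfg = WindowingConfig(window_s=10, sampling_rate=32)
    return [w for rec, track in small_cohort for w in segment(rec, track, cfg)]


@pytest.fixture(scope="session")
def windows4(small_cohort):
    cfg = WindowingConfig(window_s=4, sampling_rate=32)
    return [w for rec, track in small_cohort for w in segment(rec, track, cfg)]


@pytest.fixture(scope="session")
def time_matrix(windows4):
    return build_feature_matrix(windows4, "time")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
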