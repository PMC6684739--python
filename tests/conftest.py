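"""Shared fixtures: small synthetic cohorts reused across test modules."""

from dataclasses import replace

import pytest

from lesion2score import (
    CohortConfig,
    calibrate_noise_sd,
    default_eloquent_map,
    generate_cohort,
    generate_lesion,
)
from lesion2score.cohort import generate_clustered_cohort


@pytest.fixture(scope="session")
def emap():
    return default_eloquent_map()


@pytest.fixture(scope="session")
def small_cohort(emap):
    """20-patient synthetic cohort for harness-level tests."""
    cfg = CohortConfig(seed=7, n_patients=20)
    return generate_cohort(cfg, emap)


@pytest.fixture(scope="session")
def medium_cohort(emap):
    """40-patient cohort with moderate noise, for metric-level checks."""
    cfg = CohortConfig(seed=19, n_patients=40)
    return generate_cohort(cfg, emap)


@pytest.fixture(scope="session")
def clustered_cohort():
    """Tight lesion clusters plus singleton lesions (redundancy fixtures)."""
    return generate_clustered_cohort(seed=2)


@pytest.fixture(scope="session")
def recovery_cohort(emap):
    """n=200 cohort with noise calibrated to a generative R^2 of 0.8.

    This is the main simulation condition for parameter-recovery and
    leakage checks; built once per session.
    """
    base = CohortConfig(n_patients=200, seed=42)
    sd = calibrate_noise_sd(base, emap, target_r2=0.8)
    return generate_cohort(replace(base, noise_sd=sd), emap)


@pytest.fixture(scope="session")
def assorted_lesions():
    """A handful of lesions of assorted sizes/locations."""
    spec = [(1, (30, 36, 30), 1), (2, (13, 29, 33), 300), (3, (10, 10, 10), 100),
            (4, (50, 60, 40), 1200), (5, (45, 20, 45), 40)]
    return [generate_lesion(s, c, v) for s, c, v in spec]
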