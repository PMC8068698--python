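"""Shared fixtures for the devprofiles test suite."""

import numpy as np
import pytest
from hypothesis import settings

from devprofiles.cohort import CohortConfig, generate_cohort

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-wave cohort shared by read-only tests."""
    cfg = CohortConfig(n_subjects=400, n_items=18, seed=7)
    wave1, wave2, truth = generate_cohort(cfg)
    return cfg, wave1, wave2, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
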