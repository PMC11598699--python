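"""Shared fixtures: synthetic cohorts at the scales used across the suite.

Session scope keeps cohort generation (and the bandpass filtering inside
database construction) from being repeated per test.
"""

import numpy as np
import pytest

from neurofp import SyntheticConfig, make_cohort

# well-separated cohort: subject structure dominates run noise
EASY = dict(n_runs=4, n_rois=39, duration_s=300.0, delta=2.0, rho=0.05)
# generator defaults at short-run scale: identifiable but noisy
NOISY = dict(n_runs=4, n_rois=39, duration_s=300.0, delta=1.0, rho=0.3)


@pytest.fixture(scope="session")
def easy_cohort():
    """20 subjects x 4 runs, strong identity signal."""
    return make_cohort(SyntheticConfig(n_subjects=20, seed=0, **EASY))


@pytest.fixture(scope="session")
def easy_cohort_30():
    """30 subjects for leave-subject-out splits (20 train / 10 unseen)."""
    return make_cohort(SyntheticConfig(n_subjects=30, seed=0, **EASY))


@pytest.fixture(scope="session")
def noisy_cohort():
    """20 subjects at default separation/noise, short runs."""
    return make_cohort(SyntheticConfig(n_subjects=20, seed=3, **NOISY))


@pytest.fixture(scope="session")
def tiny_cohort():
    """5 subjects x 4 runs x 10 ROIs for fast structural tests."""
    return make_cohort(
        SyntheticConfig(n_subjects=5, n_runs=4, n_rois=10, duration_s=200.0, seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
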