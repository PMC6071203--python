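"""Shared fixtures: small deterministic cohorts and standardized matrices."""
import numpy as np
import pytest

from ecmap import CohortConfig, Mask, compute_ec_map, generate_cohort
from ecmap.synthetic import default_mask


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-sample-variance columns (the ECM convention)."""
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same draws regardless of
    # execution order
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest cohort that supports every analysis family (n > covariates)."""
    return CohortConfig(
        n_subjects=6,
        grid_dims=(12, 12, 8),
        k_networks=3,
        n_artifacts=1,
        n_timepoints_rest=60,
        n_timepoints_task=60,
        blob_sigma=1.4,
        block_seconds=15.0,
        instruction_seconds=5.0,
        trial_seconds=0.7,
        seed=5,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_ec_maps(tiny_cohort):
    return [compute_ec_map(run, tiny_cohort.mask) for run in tiny_cohort.iter_runs()]


@pytest.fixture(scope="session")
def small_mask():
    return default_mask((10, 10, 6))
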