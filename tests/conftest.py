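"""Shared fixtures: small synthetic cohorts sized for fast unit tests."""

import numpy as np
import pytest

from comareact import synthetic_cohort as sc
from comareact.montage import load_adjacency


@pytest.fixture(scope="session")
def adjacency():
    return load_adjacency()


@pytest.fixture(scope="session")
def tiny_spec():
    """A few subjects, few trials: enough structure for unit tests."""
    return sc.CohortSpec(
        n_patients=4, n_controls=3, trials_per_condition=2,
        n_rest_fragments=4, seed=42,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return sc.generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def recovery_spec():
    """Study-scale patient count with reduced epoch counts."""
    return sc.CohortSpec(
        n_patients=10, n_controls=1, trials_per_condition=3,
        n_rest_fragments=8, seed=7,
    )


@pytest.fixture(scope="session")
def recovery_cohort(recovery_spec):
    return sc.generate_cohort(recovery_spec)


@pytest.fixture(scope="session")
def patient_epoch_sets(recovery_cohort):
    return [recovery_cohort.epoch_set(s)
            for s, g in recovery_cohort.subjects() if g == "patient"]


@pytest.fixture(scope="session")
def patient_theta_contrast(patient_epoch_sets):
    from comareact import spectral

    table = spectral.condition_table(patient_epoch_sets)
    return spectral.contrast(table, "theta")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
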