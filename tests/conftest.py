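"""Shared fixtures: small synthetic cohorts and reusable fits."""

import numpy as np
import pytest

import motorprof as mp


def small_params(seed=0, n_classes=4, class_size=4, n_large=0):
    p = mp.default_params(seed=seed)
    p.n_classes_small = n_classes
    p.class_size_small = class_size
    p.n_classes_large = n_large
    p.n_schools = max(n_classes // 2, 1)
    return p


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 classes x 4 children (48 rows), deterministic."""
    table, truth = mp.generate_cohort(small_params(seed=42), seed=42)
    return table, truth


@pytest.fixture(scope="session")
def study_cohort():
    """Study layout: 23 classes of 8 + 8 classes of 16 (936 rows)."""
    table, truth = mp.generate_cohort(mp.default_params(seed=7), seed=7)
    return table, truth


@pytest.fixture(scope="session")
def study_fit(study_cohort):
    """REML fit of the final model on the study-layout cohort."""
    table, _ = study_cohort
    return mp.fit(mp.final_model_spec(), table, method="REML", seed=0)


@pytest.fixture(scope="session")
def medium_fit():
    """REML fit on a mid-size cohort (10 classes of 6) for cheap inference tests."""
    table, _ = mp.generate_cohort(small_params(seed=3, n_classes=10,
                                               class_size=6), seed=3)
    return mp.fit(mp.final_model_spec(), table, method="REML", seed=0)


def true_theta(params):
    """Log-Cholesky vector of the generating covariances relative to sigma^2."""
    s2 = params.sigma_resid ** 2
    return np.r_[mp.pack_chol(np.asarray(params.sigma_class) / s2),
                 mp.pack_chol(np.asarray(params.sigma_student) / s2)]
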