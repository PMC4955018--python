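import numpy as np
import pandas as pd
import pytest

from mtoboot import (
    GeneratorConfig,
    fit_model,
    generate_target_cohort,
    generate_training,
    load_published_coefficients,
)


@pytest.fixture(scope="session")
def published_beta():
    return load_published_coefficients()


@pytest.fixture(scope="session")
def small_config():
    """A cohort small enough for fast per-test pipelines."""
    return GeneratorConfig(n_training=3000, n_youth=600, master_seed=11)


@pytest.fixture(scope="session")
def training_sample(small_config):
    return generate_training(small_config)


@pytest.fixture(scope="session")
def cohort(small_config):
    return generate_target_cohort(small_config)


@pytest.fixture(scope="session")
def fitted_model(training_sample):
    return fit_model(training_sample)


def irls_logistic(X, y, max_iter=100, tol=1e-12):
    """Independent brute-force IRLS logistic oracle (no ridge, no reuse of
    package code): Newton-Raphson on the unpenalized log-likelihood."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = X.T @ (X * W[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta


def balanced_arm_frame(counts):
    """Build a cohort frame from per-arm (cases, non_cases) counts."""
    rows = []
    for arm, (cases, non_cases) in counts.items():
        rows += [{"arm": arm, "sex": "male", "weight": 1.0, "twelve_month": 1.0}] * cases
        rows += [{"arm": arm, "sex": "male", "weight": 1.0, "twelve_month": 0.0}] * non_cases
    return pd.DataFrame(rows)
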