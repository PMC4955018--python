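"""Multiple imputation of missing covariates and recency responses.

Runs strictly *after* outcome imputation — the pipeline's ordering contract
mirrors the original analysis, in which binary outcome imputation preceded
the 20-fold multiple imputation of missing covariates. The contract is
enforced structurally: :func:`impute_covariates` rejects any cohort whose
outcome field is still missing.

The scheme is a simple chained-equations sampler over the binary survey
fields (trauma/symptom indicators and the recency response): each cycle
refits a logistic model of one field on the demographics, the imputed
lifetime outcome, and the current values of the other survey fields, draws
a coefficient vector from the fit's asymptotic normal, and redraws the
missing entries Bernoulli at the implied probabilities. It is a stand-in by
design — the original covariate-imputation model is unknown and outside
this package's critique; any proper MI scheme serves the ensemble's purpose
of propagating mi_seed sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = ["CompletedDatasetSet", "impute_covariates", "write_completed_csv"]

#: Small ridge stabilizing the per-field logistic fits against separation
#: in sparse cells; negligible relative to the data term at cohort sizes.
_RIDGE = 1e-3


@dataclass
class CompletedDatasetSet:
    """``m`` completed copies of a cohort plus the seed that produced them.

    Non-missing fields are identical across the copies; no missing values
    remain in any copy.
    """

    m: int
    datasets: list[pd.DataFrame]
    mi_seed: int

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self) -> int:
        return self.m


def write_completed_csv(completed: "CompletedDatasetSet", path) -> None:
    """Write the M completed datasets as one long-format CSV with an
    ``imputation`` index column (1-based)."""
    long = pd.concat(
        [ds.assign(imputation=i + 1) for i, ds in enumerate(completed.datasets)],
        ignore_index=True,
    )
    cols = ["imputation"] + [c for c in long.columns if c != "imputation"]
    long[cols].to_csv(path, index=False, float_format="%.12g")


def _fit_logistic_posterior(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-6,
    start: np.ndarray | None = None,
):
    """Ridge-stabilized Newton logistic fit; returns (beta_hat, cov).

    A compact solver is used instead of a full GLM stack because the
    chained-equations loop performs thousands of small fits per ensemble;
    ``start`` warm-starts from the previous cycle's solution.
    """
    n, k = X.shape
    beta = np.zeros(k) if start is None else start.copy()
    eye = np.eye(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = p * (1.0 - p) + 1e-10
        grad = X.T @ (y - p) - _RIDGE * beta
        hess = (X * w[:, None]).T @ X + _RIDGE * eye
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    p = expit(X @ beta)
    w = p * (1.0 - p) + 1e-10
    cov = np.linalg.inv((X * w[:, None]).T @ X + _RIDGE * eye)
    return beta, cov


def _predictor_columns(frame: pd.DataFrame, survey_fields: list[str]) -> list[str]:
    base = [
        c
        for c in (
            "age",
            "sex_female",
            "race_hispanic",
            "race_black",
            "race_other",
            "lifetime_ptsd",
        )
        if c in frame.columns
    ]
    return base + survey_fields


def impute_covariates(
    cohort: pd.DataFrame,
    m: int = 20,
    mi_seed: int = 524232,
    n_cycles: int = 5,
) -> CompletedDatasetSet:
    """Draw ``m`` completed datasets by seeded chained equations.

    Parameters
    ----------
    cohort
        A cohort whose outcome field (``lifetime_ptsd``) has already been
        imputed; any binary survey field may contain missing values.
    m
        Number of completed datasets (the original analysis used 20).
    mi_seed
        Master seed; each of the ``m`` datasets uses an independent
        substream derived from it, so the set is deterministic given
        ``mi_seed`` regardless of execution order.
    n_cycles
        Chained-equation cycles per dataset.

    Raises
    ------
    ValueError
        If ``m < 1``, if the outcome field is missing or contains missing
        values (ordering contract), or if some field is 100% missing.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if "lifetime_ptsd" not in cohort.columns:
        raise ValueError(
            "cohort has no imputed outcome field; outcome imputation must "
            "precede covariate multiple imputation"
        )
    if cohort["lifetime_ptsd"].isna().any():
        raise ValueError(
            "outcome field contains missing values; outcome imputation must "
            "precede covariate multiple imputation"
        )

    missing_fields = [
        c for c in cohort.columns
        if cohort[c].isna().any() and c != "lifetime_ptsd"
    ]
    for c in missing_fields:
        if cohort[c].isna().all():
            raise ValueError(f"field {c!r} is 100% missing: no donor information")

    if not missing_fields:
        return CompletedDatasetSet(m, [cohort.copy() for _ in range(m)], mi_seed)

    predictors = _predictor_columns(cohort, missing_fields)
    n = len(cohort)
    col_of = {name: j + 1 for j, name in enumerate(predictors)}  # 0 = intercept
    base = np.column_stack(
        [np.ones(n)] + [cohort[p].to_numpy(dtype=float) for p in predictors]
    )
    miss_masks = {c: cohort[c].isna().to_numpy() for c in missing_fields}
    obs_means = {c: float(cohort[c].mean()) for c in missing_fields}
    # Fields whose observed values are constant carry no donor variability.
    constant = {
        c: float(cohort[c].dropna().iloc[0])
        for c in missing_fields
        if cohort[c].dropna().nunique() == 1
    }

    datasets: list[pd.DataFrame] = []
    warm: dict[str, np.ndarray] = {}  # per-field warm starts across cycles
    for m_idx in range(m):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=mi_seed, spawn_key=(m_idx,))
        )
        mat = base.copy()
        # Initialize missing entries from the observed marginal.
        for c in missing_fields:
            mask = miss_masks[c]
            mat[mask, col_of[c]] = (
                rng.random(mask.sum()) < obs_means[c]
            ).astype(float)
        for _ in range(n_cycles):
            for c in missing_fields:
                mask = miss_masks[c]
                if c in constant:
                    mat[mask, col_of[c]] = constant[c]
                    continue
                j = col_of[c]
                keep = [i for i in range(mat.shape[1]) if i != j]
                X = mat[:, keep]
                y_obs = base[~mask, j]
                beta_hat, cov = _fit_logistic_posterior(
                    X[~mask], y_obs, start=warm.get(c)
                )
                warm[c] = beta_hat
                # Parameter draw, then outcome draw: proper imputation.
                chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
                beta_star = beta_hat + chol @ rng.standard_normal(len(beta_hat))
                p_mis = expit(X[mask] @ beta_star)
                mat[mask, j] = (rng.random(mask.sum()) < p_mis).astype(float)
        work = cohort.copy()
        for c in missing_fields:
            work[c] = mat[:, col_of[c]]
        datasets.append(work)
    return CompletedDatasetSet(m, datasets, mi_seed)
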