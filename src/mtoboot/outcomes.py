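"""Seeded Bernoulli imputation of binary lifetime PTSD, and derivation of
the 12-month outcome via symptom recency.

This is the procedure under scrutiny: the imputation replaces each model
probability p_i with a pseudorandom draw ``1{u_i < p_i}``, destroying the
continuous information in p_i and injecting RNG noise whose magnitude the
ensemble machinery elsewhere in this package quantifies. The uniform
threshold stream is governed by a single integer ``pr_seed``, consumed in
cohort row order; the comparison is strict (``u < p``), a convention that
is measure-equivalent to any other but documented here for replay.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import CoefficientSet, predict_probabilities

__all__ = [
    "impute_lifetime",
    "derive_twelve_month",
    "cohort_probabilities",
    "impute_cohort_outcomes",
]


def impute_lifetime(probabilities, pr_seed: int) -> np.ndarray:
    """Impute binary lifetime outcomes by seeded uniform thresholds.

    ``lifetime_i = 1`` iff ``u_i < p_i`` where ``u_i`` is the i-th draw of a
    U(0,1) stream seeded with ``pr_seed`` and consumed in row order.
    Deterministic given ``pr_seed`` and the ordering of ``probabilities``.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.isnan(p).any():
        raise ValueError("probabilities contain missing values")
    if (p < 0).any() or (p > 1).any():
        bad = p[(p < 0) | (p > 1)][0]
        raise ValueError(f"probability outside [0, 1]: {bad!r}")
    u = np.random.default_rng(pr_seed).random(p.shape[0])
    return (u < p).astype(float)


def derive_twelve_month(lifetime, recency_within_12mo) -> np.ndarray:
    """12-month outcome: 0 for non-cases, the recency response for cases.

    Recency must be non-missing wherever ``lifetime == 1`` — i.e. covariate
    multiple imputation must already have filled it. A missing recency on a
    case is a pipeline-ordering bug and raises.
    """
    life = np.asarray(lifetime, dtype=float)
    rec = np.asarray(recency_within_12mo, dtype=float)
    if life.shape != rec.shape:
        raise ValueError("lifetime and recency must have equal length")
    unresolved = (life == 1.0) & np.isnan(rec)
    if unresolved.any():
        raise ValueError(
            f"{int(unresolved.sum())} imputed cases have missing recency; "
            "recency must be imputed upstream (covariate MI) first"
        )
    return np.where(life == 1.0, np.where(rec == 1.0, 1.0, 0.0), 0.0)


def cohort_probabilities(
    beta: CoefficientSet, cohort: pd.DataFrame, fill: str = "mean"
) -> np.ndarray:
    """Per-youth lifetime-PTSD probabilities under ``beta``.

    Outcome imputation runs *before* covariate multiple imputation, so some
    regressors may still be missing here (and are entirely missing for
    uninterviewed youths). For this step only, missing regressor values are
    replaced by their observed means among interviewed youths
    (``fill='mean'``), a deterministic single fill; ``fill='error'``
    propagates missingness as an error instead. The mean fill is never
    written back into the cohort.
    """
    work = cohort.copy()
    if fill == "mean":
        for name in beta.names:
            if name == "intercept" or name not in work.columns:
                continue
            col = work[name]
            if col.isna().any():
                if "interviewed" in work.columns:
                    observed = col[work["interviewed"] == 1.0].dropna()
                else:
                    observed = col.dropna()
                if observed.empty:
                    raise ValueError(f"regressor {name!r} is entirely missing")
                work[name] = col.fillna(float(observed.mean()))
    elif fill != "error":
        raise ValueError(f"unknown fill mode {fill!r}")
    return predict_probabilities(beta, work)


def impute_cohort_outcomes(
    cohort: pd.DataFrame, beta: CoefficientSet, pr_seed: int
) -> pd.DataFrame:
    """Attach ``probability``, ``lifetime_ptsd`` and ``pr_seed`` columns.

    Uninterviewed youths receive imputed outcomes like all others, matching
    the original analysis population; exclude them beforehand to pose the
    sensitivity question instead.
    """
    out = cohort.copy()
    p = cohort_probabilities(beta, cohort)
    out["probability"] = p
    out["lifetime_ptsd"] = impute_lifetime(p, pr_seed)
    out["pr_seed"] = int(pr_seed)
    return out
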