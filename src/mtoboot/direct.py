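"""Direct analysis of model probabilities, bypassing binary imputation.

If the imputation model's outputs are defended as genuine probabilities,
they can be analyzed directly — the Bernoulli-draw step only destroys
information and injects RNG noise. Two estimators are provided:

* ``fractional_logistic`` — maximizes the Bernoulli-form quasi-likelihood
  with the fractional responses p_i themselves, i.e. a quasi-binomial GLM
  of p on arm indicators (robust/HC1 standard errors, since p is not a
  genuine 0/1 outcome);
* ``linear_probability`` — weighted least squares of p on arm indicators.

Both are deterministic functions of the cohort: no seed enters anywhere,
which is the operational content of the claim that the imputation step is
superfluous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .effects import ARM_CONTRASTS

__all__ = ["DirectEffectEstimate", "direct_effect"]


@dataclass
class DirectEffectEstimate:
    arm_contrast: str
    estimate: float  # log-odds scale for fractional_logistic; probability
    # scale for linear_probability
    se: float
    method: str


def _twelve_month_probabilities(cohort: pd.DataFrame, probabilities: np.ndarray) -> np.ndarray:
    """Scale lifetime probabilities to the 12-month horizon.

    The recency response is independent of the imputation model, so the
    12-month probability is taken as p_lifetime times the observed marginal
    recency rate (model-free expectation). Recency must have been observed
    for at least one youth.
    """
    rec = cohort["recency_within_12mo"].dropna()
    if rec.empty:
        raise ValueError("no observed recency responses to estimate the 12-month rate")
    return probabilities * float(rec.mean())


def direct_effect(
    cohort: pd.DataFrame,
    weights=None,
    method: str = "fractional_logistic",
    probability_column: str = "probability",
    twelve_month: bool = True,
) -> dict[str, DirectEffectEstimate]:
    """Arm effects estimated directly from the PTSD probabilities.

    Parameters
    ----------
    cohort
        Cohort with an ``arm`` column and per-youth probabilities in
        ``probability_column`` (complete, in [0, 1]).
    weights
        Optional per-row weights; defaults to the cohort ``weight`` column
        or 1.
    method
        ``"fractional_logistic"`` (default) or ``"linear_probability"``.
    twelve_month
        When True, analyze the 12-month-scale probabilities (lifetime times
        the observed marginal recency rate); when False, the lifetime
        probabilities themselves.
    """
    if method not in ("fractional_logistic", "linear_probability"):
        raise ValueError(f"unknown method {method!r}")
    p = cohort[probability_column].to_numpy(dtype=float)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must be complete and in [0, 1]")
    if twelve_month:
        p = _twelve_month_probabilities(cohort, p)
    if weights is None:
        w = (
            cohort["weight"].to_numpy(dtype=float)
            if "weight" in cohort.columns
            else np.ones(len(cohort))
        )
    else:
        w = np.asarray(weights, dtype=float)

    arm = cohort["arm"].to_numpy()
    X = np.column_stack(
        [
            np.ones(len(cohort)),
            (arm == "traditional").astype(float),
            (arm == "low_poverty").astype(float),
        ]
    )

    if method == "fractional_logistic":
        if np.ptp(p) == 0.0:
            raise ValueError(
                "all probabilities identical: the fractional logistic fit "
                "carries no information about arm contrasts"
            )
        model = sm.GLM(p, X, family=sm.families.Binomial(), freq_weights=w)
        res = model.fit(maxiter=100, cov_type="HC1")
        params = res.params
        se = np.sqrt(np.diag(res.cov_params()))
    else:
        res = sm.WLS(p, X, weights=w).fit()
        params = res.params
        se = res.bse

    return {
        contrast: DirectEffectEstimate(contrast, float(params[i + 1]), float(se[i + 1]), method)
        for i, contrast in enumerate(ARM_CONTRASTS)
    }
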