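"""Voucher-arm effect estimation and Rubin's-rules pooling.

The estimand is the odds ratio for each voucher arm versus control on the
(imputed) 12-month PTSD outcome in boys, from a weighted logistic
regression of the outcome on two arm indicators. Estimates from the M
completed datasets are combined with Rubin's rules; 95% intervals use a
normal reference on the log-odds-ratio scale (a deliberate simplification
of the Barnard-Rubin degrees-of-freedom correction — the ensembles this
package produces are about dispersion across seeds and draws, not exact
small-sample df accounting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ARM_CONTRASTS",
    "EffectEstimate",
    "ArmDegenerateError",
    "estimate_arm_effect",
    "pool_rubin",
]

ARM_CONTRASTS: tuple[str, ...] = ("traditional_vs_control", "low_poverty_vs_control")

_Z975 = 1.959963984540054  # scipy.stats.norm.ppf(0.975)


class ArmDegenerateError(RuntimeError):
    """An arm is empty or has no outcome variation, so the arm contrast is
    unidentifiable; the message names the arm."""


@dataclass
class EffectEstimate:
    """A pooled arm-contrast estimate on the odds-ratio scale."""

    arm_contrast: str
    log_or: float
    se: float
    m_used: int = 1

    @property
    def or_point(self) -> float:
        return float(np.exp(self.log_or))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.log_or - _Z975 * self.se)),
            float(np.exp(self.log_or + _Z975 * self.se)),
        )


def estimate_arm_effect(
    dataset: pd.DataFrame,
    weights=None,
    sex_filter: str = "male",
    outcome: str = "twelve_month",
    covariates: list[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Weighted logistic regression of the outcome on arm indicators.

    Control is the reference arm. Returns ``{contrast: (log_or, se)}`` with
    Wald standard errors from the weighted information matrix. The default
    analysis population is boys (``sex_filter='male'``), interviewed or
    not; the default model is arm-only, with ``covariates`` available for
    adjusted variants.
    """
    if sex_filter not in ("male", "female", "all"):
        raise ValueError("sex_filter must be 'male', 'female' or 'all'")
    data = dataset
    if weights is None:
        w = data["weight"] if "weight" in data.columns else pd.Series(1.0, index=data.index)
    else:
        w = pd.Series(np.asarray(weights, dtype=float), index=data.index)
    if sex_filter != "all":
        keep = data["sex"] == sex_filter
        data, w = data[keep], w[keep]

    y = data[outcome].to_numpy(dtype=float)
    arm = data["arm"].to_numpy()
    for a in ("control", "traditional", "low_poverty"):
        sel = arm == a
        if not sel.any():
            raise ArmDegenerateError(f"arm {a!r} is empty")
        if y[sel].min() == y[sel].max():
            raise ArmDegenerateError(
                f"arm {a!r} has no outcome variation ({int(y[sel].sum())} cases "
                f"of {int(sel.sum())})"
            )

    cols = [
        np.ones(len(data)),
        (arm == "traditional").astype(float),
        (arm == "low_poverty").astype(float),
    ]
    names = ["intercept", "traditional", "low_poverty"]
    for c in covariates or []:
        cols.append(data[c].to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(cols)

    model = sm.GLM(
        y, X, family=sm.families.Binomial(), freq_weights=w.to_numpy(dtype=float)
    )
    res = model.fit(maxiter=100)
    if not res.converged:
        raise ArmDegenerateError("arm-effect fit failed to converge")
    se = np.sqrt(np.diag(res.cov_params()))
    return {
        "traditional_vs_control": (float(res.params[1]), float(se[1])),
        "low_poverty_vs_control": (float(res.params[2]), float(se[2])),
    }


def pool_rubin(estimates, variances, arm_contrast: str = "custom") -> EffectEstimate:
    """Combine M point estimates and within-imputation variances.

    Pooled point = mean of estimates; total variance = mean within-variance
    plus ``(1 + 1/M)`` times the between-imputation variance (sample
    variance of the estimates). Requires M >= 2 — with a single completed
    dataset there is no between-imputation variance to estimate, so use the
    single estimate directly.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be equal-length vectors")
    m = q.shape[0]
    if m < 2:
        raise ValueError(
            "Rubin pooling needs M >= 2 imputations; use the single estimate "
            "directly in single-imputation mode"
        )
    point = float(q.mean())
    within = float(u.mean())
    between = float(q.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    return EffectEstimate(arm_contrast, point, float(np.sqrt(total)), m_used=m)


def pool_arm_effects(per_imputation: list[dict[str, tuple[float, float]]]) -> dict[str, EffectEstimate]:
    """Pool :func:`estimate_arm_effect` outputs across completed datasets."""
    out = {}
    for contrast in ARM_CONTRASTS:
        est = [d[contrast][0] for d in per_imputation]
        var = [d[contrast][1] ** 2 for d in per_imputation]
        if len(per_imputation) == 1:
            out[contrast] = EffectEstimate(
                contrast, float(est[0]), float(np.sqrt(var[0])), m_used=1
            )
        else:
            out[contrast] = pool_rubin(est, var, contrast)
    return out
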