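"""Logistic lifetime-PTSD imputation model: coefficient basis, fitting,
resampling, and the alternative-specification grid.

The published imputation model is a logistic regression of lifetime PTSD
on age, sex, race, and 18 binary trauma/symptom indicators, estimated in an
adult general-population psychiatric survey and applied to a youth housing
trial cohort whose abridged interview could not support a direct diagnosis.
The coefficient vector ships as a packaged fixture
(``data/published_coefficients.csv``); its covariance was never published,
so any covariance here is estimated from (synthetic) training data or
supplied by the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "INDICATOR_NAMES",
    "RACE_LEVELS",
    "COEFFICIENT_NAMES",
    "CoefficientSet",
    "ModelSpec",
    "ConfigurationError",
    "MissingRegressorError",
    "SeparationError",
    "load_published_coefficients",
    "linear_predictor",
    "fit_model",
    "resample_coefficients",
    "build_spec_grid",
]

#: The 18 binary trauma-exposure / symptom indicators, in published order.
INDICATOR_NAMES: tuple[str, ...] = (
    "child_badly_beaten_by_caregiver",
    "badly_beaten_by_partner",
    "badly_beaten_by_other",
    "mugged_or_threatened_with_weapon",
    "ever_raped",
    "ever_sexually_assaulted",
    "someone_close_died_unexpectedly",
    "close_person_extreme_trauma",
    "child_witnessed_serious_fights",
    "saw_badly_injured_or_dead",
    "other_very_traumatic_event",
    "avoid_reminders_of_event",
    "lost_interest_in_activities",
    "emotionally_distant",
    "trouble_feeling_love",
    "no_reason_to_plan_future",
    "trouble_sleeping_random_event",
    "easily_startled",
)

#: Race is coded with an unnamed reference level plus three dummies.
RACE_LEVELS: tuple[str, ...] = ("reference", "hispanic", "black", "other")

#: Full coefficient basis of the published model (intercept + 23 regressors).
COEFFICIENT_NAMES: tuple[str, ...] = (
    "intercept",
    "age",
    "sex_female",
    "race_hispanic",
    "race_black",
    "race_other",
) + INDICATOR_NAMES


class ConfigurationError(ValueError):
    """An invalid field in a configuration object; the message names it."""


class MissingRegressorError(KeyError):
    """A covariate profile lacks a value for a model regressor.

    Raised rather than silently zero-filling: a missing regressor at
    prediction time is a pipeline-ordering bug, not a value of 0.
    """


class SeparationError(RuntimeError):
    """Logistic fit failed due to (quasi-)complete separation."""

    def __init__(self, regressors: Sequence[str]):
        self.regressors = list(regressors)
        super().__init__(
            "logistic fit did not converge to finite coefficients; "
            f"suspect regressors: {', '.join(self.regressors) or '(unknown)'}"
        )


@dataclass
class CoefficientSet:
    """A named coefficient vector, optionally with a covariance matrix.

    Parameters
    ----------
    names
        Ordered regressor labels. ``intercept`` must come first if present.
    values
        One real value per name.
    covariance
        Optional symmetric positive-semidefinite matrix aligned to ``names``.
    spec_label
        One of the specification-grid labels (``a{0,1}r{0,1}s{40,99}``) or
        ``"custom"``.
    """

    names: list[str]
    values: np.ndarray
    covariance: np.ndarray | None = None
    spec_label: str = "custom"
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(set(self.names)):
            raise ConfigurationError("coefficient names must be unique")
        if self.values.shape != (len(self.names),):
            raise ConfigurationError(
                f"values has shape {self.values.shape}, expected ({len(self.names)},)"
            )
        if self.covariance is not None:
            cov = np.asarray(self.covariance, dtype=float)
            k = len(self.names)
            if cov.shape != (k, k):
                raise ConfigurationError(
                    f"covariance has shape {cov.shape}, expected ({k}, {k})"
                )
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ConfigurationError("covariance is not symmetric within 1e-10")
            self.covariance = cov

    def __len__(self) -> int:
        return len(self.names)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names, name="value")

    def __getitem__(self, name: str) -> float:
        try:
            return float(self.values[self.names.index(name)])
        except ValueError:
            raise MissingRegressorError(name) from None

    # -- persistence ---------------------------------------------------

    def to_csv(self, path) -> None:
        """Write the two-column (name, value) delimited form."""
        df = pd.DataFrame({"name": self.names, "value": self.values})
        if self.descriptions:
            df["description"] = [self.descriptions.get(n, "") for n in self.names]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, covariance_path=None, spec_label: str = "custom") -> "CoefficientSet":
        """Read a (name, value) file; optionally a square covariance CSV
        whose header/index strings must match the names exactly."""
        df = pd.read_csv(path)
        names = df["name"].astype(str).tolist()
        values = df["value"].to_numpy(dtype=float)
        descriptions = {}
        if "description" in df.columns:
            descriptions = dict(zip(names, df["description"].fillna("").astype(str)))
        covariance = None
        if covariance_path is not None:
            cov_df = pd.read_csv(covariance_path, index_col=0)
            if list(cov_df.columns) != names or list(cov_df.index) != names:
                raise ConfigurationError(
                    "covariance file names do not match the coefficient names"
                )
            covariance = cov_df.to_numpy(dtype=float)
        return cls(names, values, covariance, spec_label, descriptions)

    def covariance_to_csv(self, path) -> None:
        if self.covariance is None:
            raise ConfigurationError("coefficient set carries no covariance")
        pd.DataFrame(self.covariance, index=self.names, columns=self.names).to_csv(path)


def load_published_coefficients() -> CoefficientSet:
    """Load the packaged published coefficient vector (24 values).

    The fixture reproduces the published table exactly; no covariance is
    attached because the original covariance matrix was never made public.
    """
    ref = resources.files("mtoboot").joinpath("data/published_coefficients.csv")
    with resources.as_file(ref) as path:
        beta = CoefficientSet.from_csv(path, spec_label="a1r1s99")
    return beta


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the 2x2x2 alternative-specification grid.

    ``include_age`` and ``include_race`` toggle the demographic regressors;
    ``training_age_cap`` optionally restricts the training sample to ages
    <= 40 before fitting (None means no restriction). The label encodes the
    three switches as ``a{0,1}r{0,1}s{40,99}``; ``a1r1s99`` is the original
    published specification.
    """

    include_age: bool
    include_race: bool
    training_age_cap: int | None

    def __post_init__(self) -> None:
        if self.training_age_cap not in (40, None):
            raise ConfigurationError("training_age_cap must be 40 or None")

    @property
    def label(self) -> str:
        s = "40" if self.training_age_cap == 40 else "99"
        return f"a{int(self.include_age)}r{int(self.include_race)}s{s}"

    @property
    def regressor_names(self) -> list[str]:
        names = ["intercept"]
        if self.include_age:
            names.append("age")
        names.append("sex_female")
        if self.include_race:
            names.extend(["race_hispanic", "race_black", "race_other"])
        names.extend(INDICATOR_NAMES)
        return names

    @classmethod
    def from_label(cls, label: str) -> "ModelSpec":
        import re

        m = re.fullmatch(r"a([01])r([01])s(40|99)", label)
        if m is None:
            raise ConfigurationError(f"unrecognized specification label {label!r}")
        return cls(
            include_age=m.group(1) == "1",
            include_race=m.group(2) == "1",
            training_age_cap=40 if m.group(3) == "40" else None,
        )


ORIGINAL_SPEC = ModelSpec(include_age=True, include_race=True, training_age_cap=None)


def build_spec_grid() -> list[ModelSpec]:
    """The eight alternative specifications, in published table order
    (age out/in varies slowest, then race, then the age-40 cap)."""
    grid = []
    for include_age in (False, True):
        for include_race in (False, True):
            for cap in (40, None):
                grid.append(ModelSpec(include_age, include_race, cap))
    return grid


# ---------------------------------------------------------------------------
# Linear predictor


def linear_predictor(beta: CoefficientSet, x: Mapping[str, float] | pd.Series) -> float:
    """Log-odds of lifetime PTSD for one covariate profile.

    Returns ``intercept + sum_j beta_j * x_j`` over the non-intercept names
    of ``beta``. The logistic transform of the result is the imputation
    probability. Every non-intercept regressor must be present in ``x`` and
    non-missing; absence raises :class:`MissingRegressorError` (never a
    silent zero-fill).
    """
    total = 0.0
    for name, value in zip(beta.names, beta.values):
        if name == "intercept":
            total += value
            continue
        try:
            xj = x[name]
        except (KeyError, IndexError):
            raise MissingRegressorError(name) from None
        if xj is None or (isinstance(xj, float) and np.isnan(xj)):
            raise MissingRegressorError(name)
        total += value * float(xj)
    return float(total)


def design_matrix(frame: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    """Assemble the model design matrix for ``names`` from a cohort/sample
    frame. ``intercept`` maps to a constant column; every other name must be
    a column of the frame with no missing values."""
    cols = []
    for name in names:
        if name == "intercept":
            cols.append(np.ones(len(frame)))
            continue
        if name not in frame.columns:
            raise MissingRegressorError(name)
        col = frame[name].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise MissingRegressorError(name)
        cols.append(col)
    return np.column_stack(cols)


def predict_probabilities(beta: CoefficientSet, frame: pd.DataFrame) -> np.ndarray:
    """Vectorized logistic probabilities for every row of ``frame``."""
    X = design_matrix(frame, beta.names)
    from scipy.special import expit

    return expit(X @ beta.values)


# ---------------------------------------------------------------------------
# Fitting


def fit_model(
    sample: pd.DataFrame,
    spec: ModelSpec = ORIGINAL_SPEC,
    outcome: str = "lifetime_ptsd",
    ridge: float = 0.0,
    regressor_names: Sequence[str] | None = None,
) -> CoefficientSet:
    """Maximum-likelihood logistic fit of the imputation model.

    The regressor set is determined by ``spec`` (age and/or race dropped
    when excluded) unless ``regressor_names`` overrides it explicitly;
    rows above the training age cap are excluded first. The returned
    :class:`CoefficientSet` carries the observed-information covariance
    matrix, which downstream coefficient resampling uses.

    No shrinkage is applied by default, mirroring the original model; pass
    ``ridge > 0`` for an optional penalized fallback after a
    :class:`SeparationError`.
    """
    data = sample
    if spec.training_age_cap is not None:
        data = data[data["age"] <= spec.training_age_cap]
    names = list(regressor_names) if regressor_names is not None else spec.regressor_names
    X = design_matrix(data, names)
    y = data[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise SeparationError([outcome])

    if ridge > 0.0:
        res = sm.Logit(y, X).fit_regularized(
            alpha=ridge, L1_wt=0.0, disp=0, maxiter=200
        )
        params = np.asarray(res.params, dtype=float)
        cov = np.asarray(sm.Logit(y, X).hessian(params), dtype=float)
        cov = np.linalg.inv(-cov + ridge * np.eye(len(names)))
    else:
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=100)
        params = np.asarray(res.params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
        if not res.converged or not np.all(np.isfinite(params)):
            bad = [n for n, p in zip(names, params) if not np.isfinite(p) or abs(p) > 15]
            raise SeparationError(bad or names)
        # Quasi-complete separation shows up as huge coefficients/SEs.
        se = np.sqrt(np.diag(cov))
        suspect = [
            n
            for n, p, s in zip(names, params, se)
            if n != "intercept" and (abs(p) > 15 or s > 50)
        ]
        if suspect:
            raise SeparationError(suspect)

    cov = 0.5 * (cov + cov.T)  # enforce exact symmetry of the inverse
    return CoefficientSet(names, params, cov, spec_label=spec.label)


# ---------------------------------------------------------------------------
# Coefficient resampling


def _psd_factor(cov: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Square root of a (near-)PSD matrix via symmetrization + eigen-clip.

    Negative eigenvalues within ``tol`` of zero (relative to the largest)
    are clipped; anything more negative is a genuine non-PSD input and
    raises.
    """
    sym = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(sym)
    scale = max(abs(w).max(), 1.0)
    if w.min() < -tol * scale:
        raise ConfigurationError(
            f"covariance is not positive semidefinite (min eigenvalue {w.min():.3g})"
        )
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def resample_coefficients(
    beta: CoefficientSet, k: int, seed: int
) -> list[CoefficientSet]:
    """Draw ``k`` coefficient vectors from MVN(values, covariance).

    The first element is replaced by the point-estimate values themselves,
    so the first ensemble cell embeds an exact reproduction of the original
    point-estimate analysis. Deterministic given ``seed``.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if beta.covariance is None:
        raise ConfigurationError(
            "coefficient resampling requires a covariance matrix; "
            "fit_model attaches one"
        )
    factor = _psd_factor(beta.covariance)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((k, len(beta)))
    draws = beta.values[None, :] + z @ factor.T
    draws[0] = beta.values
    return [
        replace(beta, values=draws[i], covariance=None) for i in range(k)
    ]
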