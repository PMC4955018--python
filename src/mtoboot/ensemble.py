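"""Bootstrap ensembles over coefficient draws, RNG seeds, and model
specifications.

Two ensembles contextualize the single published point estimate:

* the **coefficient-resampling ensemble** redraws the imputation-model
  coefficients from their estimated sampling distribution (first draw =
  the point estimate itself) and crosses them with a grid of outcome-
  imputation seeds (``pr_seed``) and covariate-MI seeds (``mi_seed``) —
  10 x 5 x 10 = 500 cells under the defaults;
* the **specification ensemble** replaces coefficient redraws with the
  eight-member alternative-specification grid — 8 x 5 x 10 = 400 cells.

Each cell derives its RNG streams solely from its own (draw index,
pr_seed, mi_seed) coordinates, never from a shared sequential stream, so
cells may run in any order (or concurrently) and the replication cell —
the cell at the originally published seed pair with the original
coefficients/specification — is bit-identical whether run standalone or
inside the full grid.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import ARM_CONTRASTS, EffectEstimate, pool_arm_effects, estimate_arm_effect
from .mi import impute_covariates
from .model import (
    CoefficientSet,
    ConfigurationError,
    ModelSpec,
    build_spec_grid,
    fit_model,
    resample_coefficients,
)
from .outcomes import derive_twelve_month, impute_cohort_outcomes

__all__ = [
    "EnsembleConfig",
    "EnsembleCell",
    "run_cell",
    "run_coefficient_ensemble",
    "run_specification_ensemble",
    "summarize_ensemble",
    "cells_to_frame",
    "plot_ensemble",
]

logger = logging.getLogger("mtoboot.ensemble")

#: Seed grids of the reanalysis: five outcome-imputation seeds (the last is
#: the originally published one) and ten consecutive covariate-MI seeds
#: bracketing the originally published 524232.
DEFAULT_PR_SEEDS: tuple[int, ...] = (123, 1234, 12345, 123456, 1234567)
DEFAULT_MI_SEEDS: tuple[int, ...] = tuple(range(524230, 524240))
REPLICATION_PR_SEED = 1234567
REPLICATION_MI_SEED = 524232


@dataclass
class EnsembleConfig:
    mode: str = "coefficient_resampling"
    n_coef_draws: int = 10
    pr_seeds: list[int] = field(default_factory=lambda: list(DEFAULT_PR_SEEDS))
    mi_seeds: list[int] = field(default_factory=lambda: list(DEFAULT_MI_SEEDS))
    m_imputations: int = 20
    coef_draw_seed: int = 2016
    sex_filter: str = "male"

    def __post_init__(self) -> None:
        if self.mode not in ("coefficient_resampling", "specification_grid"):
            raise ConfigurationError(f"unknown ensemble mode {self.mode!r}")
        if len(set(self.pr_seeds)) != len(self.pr_seeds):
            raise ConfigurationError("pr_seeds contains duplicates")
        if len(set(self.mi_seeds)) != len(self.mi_seeds):
            raise ConfigurationError("mi_seeds contains duplicates")
        if self.n_coef_draws < 1:
            raise ConfigurationError("n_coef_draws must be >= 1")
        if self.m_imputations < 1:
            raise ConfigurationError("m_imputations must be >= 1")


@dataclass
class EnsembleCell:
    """One grid point: a (draw or spec, pr_seed, mi_seed) triple with its
    pooled effect estimates, or the error that prevented them."""

    index: int | str  # 1-based draw index, or specification label
    pr_seed: int
    mi_seed: int
    estimates: dict[str, EffectEstimate] | None = None
    error: str | None = None
    is_replication_cell: bool = False
    provenance: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.error is None and self.estimates is not None


def run_cell(
    cohort: pd.DataFrame,
    beta: CoefficientSet,
    pr_seed: int,
    mi_seed: int,
    m: int = 20,
    sex_filter: str = "male",
) -> dict[str, EffectEstimate]:
    """Execute one cell: outcome imputation, covariate MI, per-dataset
    effect estimation, Rubin pooling. Deterministic in (beta, seeds)."""
    imputed = impute_cohort_outcomes(cohort, beta, pr_seed)
    completed = impute_covariates(imputed, m=m, mi_seed=mi_seed)
    per_imp = []
    for ds in completed:
        ds = ds.copy()
        ds["twelve_month"] = derive_twelve_month(
            ds["lifetime_ptsd"], ds["recency_within_12mo"]
        )
        per_imp.append(estimate_arm_effect(ds, sex_filter=sex_filter))
    return pool_arm_effects(per_imp)


def _run_grid(cohort, items, config: EnsembleConfig, provenance_of) -> list[EnsembleCell]:
    cells: list[EnsembleCell] = []
    for index, beta in items:
        for pr_seed in config.pr_seeds:
            for mi_seed in config.mi_seeds:
                is_rep = (
                    pr_seed == REPLICATION_PR_SEED
                    and mi_seed == REPLICATION_MI_SEED
                    and (index == 1 or index == "a1r1s99")
                )
                t0 = time.perf_counter()
                cell = EnsembleCell(
                    index, pr_seed, mi_seed,
                    is_replication_cell=is_rep,
                    provenance=provenance_of(index),
                )
                try:
                    cell.estimates = run_cell(
                        cohort, beta, pr_seed, mi_seed,
                        m=config.m_imputations, sex_filter=config.sex_filter,
                    )
                except Exception as exc:  # estimation failure stays cell-local
                    cell.error = f"{type(exc).__name__}: {exc}"
                logger.info(
                    "cell index=%s pr_seed=%d mi_seed=%d status=%s runtime=%.2fs",
                    index, pr_seed, mi_seed,
                    "ok" if cell.ok else "error", time.perf_counter() - t0,
                )
                cells.append(cell)
    return cells


def run_coefficient_ensemble(
    cohort: pd.DataFrame, fitted_model: CoefficientSet, config: EnsembleConfig
) -> list[EnsembleCell]:
    """The coefficient-resampling ensemble.

    ``fitted_model`` must carry a covariance matrix; ``n_coef_draws``
    coefficient vectors are drawn from its asymptotic normal (draw 1 being
    the point estimate itself) and crossed with the seed grids.
    """
    draws = resample_coefficients(
        fitted_model, config.n_coef_draws, config.coef_draw_seed
    )
    items = [(d + 1, beta) for d, beta in enumerate(draws)]
    return _run_grid(
        cohort, items, config,
        provenance_of=lambda index: {"draw_index": index, "spec_label": fitted_model.spec_label},
    )


def run_specification_ensemble(
    training_sample: pd.DataFrame, cohort: pd.DataFrame, config: EnsembleConfig,
    specs: list[ModelSpec] | None = None,
) -> list[EnsembleCell]:
    """The specification ensemble: refit the imputation model under each
    alternative specification (with its training-age subsetting), then run
    the seed grid for each."""
    specs = build_spec_grid() if specs is None else specs
    items = []
    provenance = {}
    for spec in specs:
        data = training_sample
        if spec.training_age_cap is not None:
            data = data[data["age"] <= spec.training_age_cap]
        beta = fit_model(training_sample, spec)
        provenance[spec.label] = {
            "spec_label": spec.label,
            "training_rows": int(len(data)),
            "training_max_age": float(data["age"].max()),
        }
        items.append((spec.label, beta))
    return _run_grid(cohort, items, config, provenance_of=lambda label: dict(provenance[label]))


# ---------------------------------------------------------------------------
# Summaries


def cells_to_frame(cells: list[EnsembleCell]) -> pd.DataFrame:
    """Flatten cells to one row per (cell, arm contrast) for CSV output."""
    rows = []
    for cell in cells:
        for contrast in ARM_CONTRASTS:
            row = {
                "index": cell.index,
                "pr_seed": cell.pr_seed,
                "mi_seed": cell.mi_seed,
                "arm_contrast": contrast,
                "is_replication_cell": int(cell.is_replication_cell),
                "error": cell.error or "",
            }
            if cell.ok:
                est = cell.estimates[contrast]
                lo, hi = est.ci95
                row.update(
                    log_or=est.log_or, se=est.se, or_point=est.or_point,
                    ci_low=lo, ci_high=hi, m_used=est.m_used,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def _variance_components(frame: pd.DataFrame) -> dict[str, float]:
    """Crude crossed decomposition: the variance of factor-level means of
    log-OR for each grid factor, plus the residual against the total."""
    total = float(frame["log_or"].var(ddof=0))
    comps = {}
    for factor in ("index", "pr_seed", "mi_seed"):
        comps[factor] = float(frame.groupby(factor)["log_or"].mean().var(ddof=0))
    residual = max(total - sum(comps.values()), 0.0)
    return {"total": total, **comps, "residual": residual}


def summarize_ensemble(cells: list[EnsembleCell]) -> dict:
    """Summarize the cloud of estimates.

    Per arm contrast: the fraction of cells whose 95% CI lower bound
    exceeds OR = 1 (the "randomly selected CI sits above 1" rate), OR
    range and quantiles, and a variance decomposition of log-OR across the
    grid factors by group means. Order-invariant in the cells.
    """
    ok = [c for c in cells if c.ok]
    if not ok:
        raise ValueError("no successful cells to summarize")
    frame = cells_to_frame(ok)
    out: dict = {
        "n_cells": len(cells),
        "n_successful": len(ok),
        "n_failed": len(cells) - len(ok),
        "contrasts": {},
    }
    for contrast in ARM_CONTRASTS:
        sub = frame[frame["arm_contrast"] == contrast].sort_values(
            ["index", "pr_seed", "mi_seed"]
        )
        ors = sub["or_point"].to_numpy()
        qs = np.quantile(ors, [0.025, 0.25, 0.5, 0.75, 0.975])
        out["contrasts"][contrast] = {
            "fraction_ci_above_1": float((sub["ci_low"] > 1.0).mean()),
            "or_min": float(ors.min()),
            "or_max": float(ors.max()),
            "or_quantiles": {
                "q025": float(qs[0]), "q25": float(qs[1]), "q50": float(qs[2]),
                "q75": float(qs[3]), "q975": float(qs[4]),
            },
            "log_or_variance_components": _variance_components(sub),
        }
    rep = [c for c in ok if c.is_replication_cell]
    if rep:
        out["replication_cell"] = {
            contrast: {
                "or_point": rep[0].estimates[contrast].or_point,
                "ci95": list(rep[0].estimates[contrast].ci95),
            }
            for contrast in ARM_CONTRASTS
        }
    return out


def plot_ensemble(
    cells: list[EnsembleCell],
    path,
    contrast: str = "low_poverty_vs_control",
) -> None:
    """Faceted dot-and-interval panel plot on a logarithmic OR axis.

    Facet rows are mi_seed, facet columns pr_seed; within each panel one
    dot-and-interval per draw/spec. The replication cell is highlighted in
    red; the OR = 1 reference line is dashed.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = [c for c in cells if c.ok]
    if not ok:
        raise ValueError("no successful cells to plot")
    mi_seeds = sorted({c.mi_seed for c in ok})
    pr_seeds = sorted({c.pr_seed for c in ok})
    indices = sorted({c.index for c in ok}, key=str)
    ypos = {idx: i for i, idx in enumerate(indices)}

    fig, axes = plt.subplots(
        len(mi_seeds), len(pr_seeds),
        figsize=(2.2 * len(pr_seeds) + 1, 1.1 * len(mi_seeds) + 1),
        sharex=True, sharey=True, squeeze=False,
    )
    for c in ok:
        ax = axes[mi_seeds.index(c.mi_seed)][pr_seeds.index(c.pr_seed)]
        est = c.estimates[contrast]
        lo, hi = est.ci95
        color = "red" if c.is_replication_cell else "steelblue"
        y = ypos[c.index]
        ax.plot([lo, hi], [y, y], color=color, lw=1)
        ax.plot([est.or_point], [y], "o", color=color, ms=3)
    for i, mi in enumerate(mi_seeds):
        axes[i][0].set_ylabel(f"mi {mi}", fontsize=7)
        for j, pr in enumerate(pr_seeds):
            ax = axes[i][j]
            ax.axvline(1.0, ls="--", color="gray", lw=0.7)
            ax.set_xscale("log")
            ax.tick_params(labelsize=6)
            if i == 0:
                ax.set_title(f"pr {pr}", fontsize=7)
            ax.set_yticks([])
    fig.suptitle(f"Ensemble of {contrast} odds ratios (log scale)", fontsize=9)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
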