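# Methods

## The problem

In a large housing-mobility randomized trial, the psychiatric outcome of
interest — 12-month PTSD in adolescent boys — was never directly observed.
The survey instrument was an abridged diagnostic interview, so a lifetime
PTSD "outcome" was *imputed*: a logistic regression of lifetime PTSD on
age, sex, race and 18 retained trauma/symptom items, estimated in an adult
general-population survey, was evaluated on each youth, and the resulting
probability was converted to a binary diagnosis by a single pseudorandom
Bernoulli draw. A recency response then converted lifetime to 12-month
status, missing covariates were multiply imputed (after the outcome
imputation, not before), and voucher-arm odds ratios were pooled over the
M = 20 completed datasets with Rubin's rules.

Because a logistic regression has no error term, the confidence interval
of the resulting arm effect reflects only the RNG noise injected by the
Bernoulli step. `mtoboot` implements this entire chain as tested,
replayable code, together with the bootstrap machinery that places the
single published estimate inside the ensemble of estimates it could just
as well have been: resampling the imputation-model coefficients from
their asymptotic normal, varying the outcome-imputation seed (`pr_seed`)
and the covariate-MI seed (`mi_seed`), and swapping among eight
alternative model specifications.

## Pipeline stages and their contracts

1. **Imputation model** (`mtoboot.model`). The published 24-coefficient
   vector ships as a packaged fixture; `linear_predictor` is exact and
   refuses missing regressors (no silent zero-fill). `fit_model` is an
   unpenalized ML logistic fit (statsmodels GLM) that attaches the
   observed-information covariance; (quasi-)separation raises an error
   naming the suspect regressors, with an optional ridge fallback that is
   off in replication mode — the original model applied no shrinkage.
   `resample_coefficients` draws from MVN(point estimate, covariance)
   after symmetrization and eigen-clipping of near-zero negative
   eigenvalues; the first draw is always replaced by the point estimate so
   that one ensemble cell is the exact reproduction of the original
   analysis. The covariance is always an estimate from (synthetic)
   training data or user-supplied: the original covariance was privately
   communicated and is not public.

2. **Outcome imputation** (`mtoboot.outcomes`). `impute_lifetime` compares
   seeded U(0,1) draws to the probabilities in cohort row order, with the
   strict convention `u < p` (any fixed convention is measure-equivalent;
   strictness is documented for replay). Because outcome imputation
   precedes covariate MI, probabilities are computed with missing
   regressors replaced by their observed means among interviewed youths —
   a deterministic fill used *only* for this step and never written back.
   Uninterviewed youths receive imputed outcomes like everyone else,
   matching the original analysis population. Seed values are arbitrary
   labels of RNG streams; only determinism within this package is
   promised, not reproduction of any other platform's RNG stream.

3. **Covariate MI** (`mtoboot.mi`). A chained-equations sampler over the
   binary survey fields: per field, a ridge-stabilized Newton logistic fit
   (ridge 1e-3, negligible at cohort sizes) on demographics, the imputed
   outcome, and the other fields' current values; a coefficient draw from
   the fit's asymptotic normal; then Bernoulli redraws of the missing
   entries. Five cycles, M = 20 by default (configurable to 1000). Each of
   the M datasets uses an independent substream spawned from `mi_seed`.
   This scheme is a stand-in by design: the original covariate-imputation
   model is unknown and explicitly outside the critique; any proper MI
   scheme serves the ensemble's purpose. The ordering contract is
   structural: `impute_covariates` rejects cohorts whose outcome field is
   still missing.

4. **Effect estimation** (`mtoboot.effects`). Weighted logistic regression
   of the 12-month outcome on two arm indicators (control reference),
   boys by default, Wald SEs from the weighted information matrix
   (frequency weights). Rubin pooling uses the normal reference rather
   than Barnard–Rubin degrees of freedom: the package's purpose is
   ensemble dispersion, not exact small-sample df accounting, and the
   simplification is deliberate. The default model is arm-only; the
   original adjustment set is not documented, and a covariate list is
   accepted for adjusted variants.

5. **Ensembles** (`mtoboot.ensemble`). Grids are 10 draws x 5 pr_seeds x
   10 mi_seeds = 500 cells (coefficient resampling) and 8 specs x 5 x 10
   = 400 cells (specification grid), with the replication cell at
   (draw 1 or spec a1r1s99, pr_seed 1234567, mi_seed 524232). Cell-level
   failures are recorded in the cell, never fatal to the grid. Seed
   isolation is a contract: each cell's RNG streams derive solely from its
   own coordinates, so execution order is irrelevant and the replication
   cell is bit-identical standalone or in-grid. The summary reports the
   fraction of cells whose CI lower bound exceeds OR = 1, OR quantiles,
   and a variance decomposition of log-OR by factor-level group means
   (draw/spec, pr_seed, mi_seed, residual). No single pooled "wider CI"
   is computed from the cells: the seed-clustered variance structure makes
   such an interval meaningless, which is part of the point.

6. **Direct analysis** (`mtoboot.direct`). The seed-free alternative:
   analyze the probabilities themselves. Default estimator is fractional
   (quasi-binomial) logistic with robust SEs; a linear probability model
   is the alternative. The 12-month restriction on the probability scale
   multiplies the lifetime probability by the observed marginal recency
   rate (a model-free expectation), separable by flag.

7. **Reporting** (`mtoboot.reporting`). A JSON manifest binds each run to
   its generator config, ensemble config, replication-cell estimate and
   SHA-256 digests of the output files; `replay` reruns the pipeline from
   the manifest and verifies digests, localizing any divergence to the
   affected grid cells.

The command-line layer (`mtoboot` entry point: `simulate`, `fit`,
`ensemble`, `report`, `replay`) is a thin wrapper over these functions.

## The synthetic generator

No public data exist for this pipeline (the trial data are
license-restricted), so `mtoboot.synthetic` generates both samples with
the structure the analysis assumes:

* **Training sample**: independent Bernoulli(0.15) trauma/symptom
  indicators, uniform adult ages 18–99, sex ~ Bernoulli(0.5), a four-level
  race mix (45/20/25/10%), and lifetime PTSD drawn at the logistic
  probability implied by a known coefficient vector — by default the
  published vector itself. Recency is Bernoulli(0.5) among cases only.
* **Youth cohort**: default n = 1,863 youths in households of 1–3
  (uniform), household-level randomization to three equal-probability
  arms, adolescent ages 13–20 (barely overlapping the training ages),
  24.5% uninterviewed (losing all survey fields, keeping baseline fields),
  and MCAR masking of survey fields at 10% among the interviewed. Each
  youth carries a *latent* lifetime-PTSD status whose log-odds include an
  arm shift (defaults 0.985 traditional / 1.224 low-poverty, i.e. latent
  odds ratios of roughly 2.7 and 3.4); latent truths are test
  instrumentation, invisible to the pipeline. Weights default to 1.0, with
  an optional lognormal mode for exercising weighted estimation — the
  original precomputed survey weights are out of scope.

What the generator deliberately does **not** emulate: correlation among
the trauma items, arm-dependent survey responses, informative
missingness, the five-city structure, or calibrated marginal prevalences
(no such prevalence is published; the synthetic lifetime prevalence that
follows mechanically from the published coefficients over this covariate
mix is high, ~50–60%, and is left uncalibrated). Two consequences matter
for interpreting tests:

* Because the imputation model contains no arm term and synthetic
  covariates are arm-independent, imputation-based arm effects center on
  OR = 1 regardless of the latent arm shift. This is faithful to the
  mechanism — an imputed outcome can reflect treatment only through
  arm-covariate differences — but it means the synthetic ensembles probe
  the *dispersion* machinery, not the published effect sizes.
* Passing tests demonstrate correctness of the machinery and its
  contracts on data with this structure, not reproduction of the
  restricted-data results: the published headline odds ratios
  (3.44 [1.60–7.39]; 2.68 [1.23–5.82]) require the restricted data
  package and the private covariance, and are not targets here.

## Numerical choices

* Logistic fits: statsmodels GLM/IRLS for the public fitting surfaces;
  the MI engine uses a compact warm-started Newton solver (tolerance
  1e-6) because ensembles perform hundreds of thousands of small fits.
  Equivalence with an independently coded IRLS oracle is asserted to
  1e-6 in the tests.
* Separation detection: non-convergence, non-finite parameters, or
  |coef| > 15 / SE > 50 on a non-intercept term.
* PSD repair in resampling: symmetrize, then clip negative eigenvalues
  within 1e-8 (relative) of zero; anything more negative is an error.
* RNG: NumPy `SeedSequence`-spawned `default_rng` streams keyed by stage
  and cell coordinates; all outputs are pure functions of the configs.
* CSV outputs are written with `%.17g` floats so digests see full
  precision; YAML configs round-trip bit-exactly.
* Test and example problem sizes: ensembles are exercised at a reduced
  cohort of ~2,000 youths with M = 5, parameter recovery at n = 20,000
  over 200 draws, and null coverage over 500 replicate cohorts — sizes
  chosen to make the full suite a desk-scale run while keeping Monte
  Carlo bands tight.

## Known limitations

* The exact wording/skip logic of the 18 survey items is unrecoverable;
  the snake_case names map 1:1 to the published row text (kept in the
  fixture's `description` column).
* The recency derivation is modeled as a single binary response; how the
  original thresholded "recency of symptoms" at 12 months is unspecified.
* Rubin CIs use a normal reference (see above).
* The MI scheme and its regressor set are stand-ins; congeniality
  diagnostics are out of scope.
* The race reference category is the unnamed level implied by the three
  published dummies; the generator labels it "reference".
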