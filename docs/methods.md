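# Methods

## Metrics and conventions

A repertoire is a multiset of clone template counts. The package computes
size `S` (sum of counts), diversity `D` (number of distinct clones) and
top-k mass `S_k` (sum of the k largest counts), with `P_k = 100 * S_k / S`.
All logarithms are base 10; scatter is quoted in dex.

Conventions adopted where the definitions leave room:

- **Ties at rank k.** Tied counts contribute equal mass, so `S_k` is
  unambiguous; the *identity* of the selected clones is made deterministic
  by breaking ties on clone id (needed only by `top_k_clone_set`).
- **k ≥ D.** `S_k = S` and `P_k = 100`: when fewer than k clones exist,
  the "k most abundant clones" are all of them.
- **Counts are integers.** `S` counts sequenced cells; fractional
  abundances are rejected rather than rounded, so file-format errors
  surface instead of silently renormalising.
- Clone identity is opaque (nucleotide- vs amino-acid-level clonotype
  definitions are left to the input file); no V/D/J or CDR3 handling.

## The constructive cohort generator

The analysis consumes only `(S, D, S_k)` per subject, so the generator
targets those metrics directly instead of simulating clonal dynamics. A
target triple is *feasible* iff every clone can hold ≥ 1 template
(`S_k ≥ k`, `S − S_k ≥ D − k`) and no rank inversion is forced:
`floor(S_k/k) ≥ ceil((S−S_k)/(D−k))` when `D > k`. The constructor
distributes the tail mass as evenly as possible over the `D − k` tail
clones and the top mass either evenly or with a geometric rank-abundance
decay (for heavier heads); geometric profiles are repaired by raising
deficient top clones to the tail ceiling and trimming the largest, so
`compute_metrics ∘ construct_clone_table` is the identity for any feasible
triple and either profile. This exactness is the package's main test
lever: every downstream statistic can be checked against known ground
truth.

Per subject the generator draws covariates (age uniform on 20–80 years,
47.2% male, CMV seropositivity rising with age from 20% at 0.6%/year),
then:

1. `log10 S ~ Normal(mu_S, 0.14)` where `mu_S` carries an age slope of
   −0.003 dex/yr and a +0.08 dex CMV offset. The configured median
   (log₁₀ 518,618) is the *cohort-marginal* median: covariate effects are
   median-centred so they reshape the cohort without displacing it.
2. Clonality target `P_k` (percent): 10 at age 20 rising by 1/3 per year
   (30 at age 80), −3 for females, +5 for CMV-positive, Gaussian noise
   sd 5, clipped to [0.5, 80]. `S_k = round(P_k · S / 100)`.
3. Diversity. Default (`d_link="linear"`): `D` from
   `0.825·S − 0.965·S_k` with 0.015 dex intrinsic noise and 0.027 dex
   measurement noise on `log10 D` — covariates affect `D` only through
   size and clonality, the mediation structure the models are designed to
   detect. Alternative (`d_link="lognormal"`): `(log10 S, log10 D)`
   bivariate normal (correlation 0.7, `sd_D` 0.177 dex) with direct age,
   sex and CMV effects on `D`, for studies of the descriptive statistics
   in isolation.
4. Infeasible triples (rare at these scales) are projected onto the
   feasible set — `S_k` adjusted first, then `D` — and counted; if more
   than half the cohort needs projection the parameter set is rejected as
   inconsistent.

The dispersions derive from the stated central-95% spans of the cohort
being emulated (0.58 dex for `S`, 0.70 dex for `D`, giving marginal sds of
~0.15 and ~0.18 dex); the noise scales are chosen so the generative world
is arithmetically coherent with the published error budget (see
*Measurement error* below). Reproducibility: one global seed; per-subject
substreams are spawned from it, so cohorts are reproducible and subjects
independent.

**What the generator does not emulate.** Real within-repertoire
rank-abundance shapes beyond the top-k/tail split (the even and geometric
profiles are schematic); CMV-specific covariance between expansion and
size *within* the seropositive stratum (CMV enters as constant offsets, so
the simulated CMV-positive S–P correlation is not attenuated the way real
cohorts show); depth-driven undersampling of richness unless multinomial
subsampling is explicitly enabled (`depth=`); batch effects, longitudinal
structure, HLA, and clonotype sequence content. Passing tests on this
generator therefore demonstrate correctness of the estimators under the
assumed statistical structure, not robustness to everything real data do.

### Subsampling and replicates

`subsample_repertoire` models sequencing at a stated depth as a
multinomial draw over clone frequencies (or multivariate hypergeometric
without replacement); observed richness is then a biased-down,
depth-monotone estimate of true richness, which tests verify against exact
enumeration on toy repertoires. `simulate_replicates` perturbs `log10 D`
per measurement with independent Gaussian noise at fixed `S`, so pair
differences in `log10(D/S)` have sd `noise_sd·√2`; it is deliberately a
noise model, not a re-sequencing simulation, because its role is to
calibrate the MAE estimator.

## Binned medians and correlations

Curves are medians of a metric in fixed bins of a covariate (decade-wide
age bins from 20 by default; edges configurable). Uncertainty is a
percentile bootstrap within each bin (default 1,000 resamples, 95%
interval) — the simplest defensible variant where the bootstrap flavour is
not otherwise pinned down. Central 25–75% and 5–95% bands are empirical
quantiles. Bins with fewer than 20 subjects are flagged and reported as
NaN rather than dropped, so sparse strata remain visible. Spearman
correlations use mid-rank tie handling (scipy) with two-sided p-values;
constant inputs raise rather than returning NaN.

## Diversity models

**Linear model.** `D = a·S − b·S_k`, no intercept, fitted by least squares
on untransformed counts (an optional intercept flag exists, default off).
Coefficients come from fitting all data; their 1σ uncertainties from a
nonparametric pairs bootstrap (default 1,000 resamples); predictions and
R² from five-fold cross-validation (subjects shuffled once by seed and
split into folds, no stratification), so every subject is predicted
exactly once by a model that never saw it. An exactly collinear or
constant regressor raises a collinearity error. Because the fit is on raw
counts but the error budget is in dex, the residual scatter is reported
both ways: `residual_sd_dex` (sd of `log10 D − log10 D̂` from the
full-data fit — the headline, feeding the decomposition) and
`residual_sd_raw`; R² is likewise reported on both scales.

**Gradient-boosted model.** `XGBRegressor` at default hyperparameters with
squared-error loss; sex is a {0,1} indicator, CMV status becomes
`cmv_positive` plus a separate `cmv_unknown` indicator (no imputation).
Out-of-fold predictions use the same five-fold scheme; importances (gain,
normalised to sum 1) come from a fit on all data and can be re-grouped
onto the original categorical features. No tuning is performed: default
behaviour is part of the method. One consequence, verified in tests: on a
permuted target the default trees overfit noise, so out-of-fold R² is
mildly *negative* — the null check asserts absence of positive skill, not
R² ≈ 0 exactly.

**Top-k sensitivity** refits the linear model with `S_10` or `S_100` in
place of `S_1000` and compares cross-validated R²; under the generative
link the k = 1000 fit is never worse.

## Measurement error and intrinsic scatter

The MAE is taken literally as the sample sd (ddof = 1) of pair differences
in `log10(D/S)` — *not* divided by √2 — because the decomposition
`σ_i = √(σ_r² − σ_m²)` compares that difference-scale quantity directly
with the model residual sd; an optional flag returns the √2-corrected
per-measurement sd for users who want the conventional quantity. To keep
the synthetic world coherent with this convention, the defaults set
per-subject measurement noise on cohort `log10 D` to 0.027 dex and
replicate per-measurement noise to 0.027/√2 (pair-difference sd 0.027):
the decomposition then recovers the injected 0.015 dex intrinsic scatter
from a 0.031 dex residual. If the estimated floor exceeds the residual,
the decomposition raises an over-subtraction error rather than silently
returning 0 or NaN. The unexplained fraction is reported two ways —
`1 − R²(CV)` (the headline) and the variance ratio
`(σ_i / σ_total)²` with the cohort dispersion itself quadrature-corrected —
because the two definitions differ and the package does not privilege one
beyond labelling. Decomposition outputs carry full precision; display
rounds to two significant figures.

## Numerical choices

- Feasibility projection order: `S_k` first (clonality is the softest
  target), then `D`; projections are logged and counted.
- `D̂ ≤ 0` from a CV fold (possible at extreme clonality) is floored at 1
  before taking logs.
- Degenerate inputs raise typed errors (`EmptyInputError`,
  `DegenerateInputError`, `CollinearityError`, `OverSubtractionError`, …)
  instead of propagating NaNs.
- Bootstrap and CV randomness always flow from explicit seeds; the CLI
  records config hash, seed and package version in a manifest per run.

## Problem sizes

The test suite exercises cohorts of 400–10,000 subjects, 100-replicate
coverage runs at n = 400, exhaustive round-trip enumeration to S ≤ 40
plus thousands of randomised triples up to S = 2×10⁶, and 10⁵ Monte-Carlo
subsampling draws; `scripts/acceptance.py` runs the full analysis at the
30,430-subject study scale. These sizes make every stochastic check
converge well inside its Monte-Carlo tolerance while keeping a complete
run to a few minutes on one CPU.

## Known limitations

- The generator's realism is metric-level only (see above); it cannot
  validate clone-level analyses.
- The no-intercept linear model is heteroscedastic in raw counts
  (multiplicative dex noise grows with `D`); ordinary least squares is
  used regardless because the model form, not efficiency, is the contract.
  The pairs bootstrap keeps the SEs honest under this heteroscedasticity.
- `estimate_mae` assumes replicate pairs are exchangeable and
  measurement errors independent between pair members; correlated
  replicate errors would inflate neither the estimate nor the residual
  consistently.
- Cohort tables are held in memory as pandas DataFrames; repertoire files
  are processed one at a time, so memory scales with the largest single
  repertoire, not the cohort.
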