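# tcrdiv

Tools for analysing T cell receptor β-chain (TCRβ) repertoire diversity in
large immunosequencing cohorts.

A blood sample's TCRβ repertoire is summarised by three numbers: the
repertoire size *S* (total T cell templates sequenced), the diversity *D*
(number of unique clonotypes, i.e. richness), and the top-*k* clone mass
*S*<sub>k</sub> (templates carried by the *k* most abundant clones;
*P*<sub>k</sub> = 100·*S*<sub>k</sub>/*S* expresses it as a percentage and
serves as a proxy for repertoire-wide clonal expansion — "intrinsic
clonality"). Although *S*, *D* and *P*<sub>1000</sub> each depend on age,
sex and CMV serostatus, diversity is almost fully determined by size and
clonality through the no-intercept linear model

&nbsp;&nbsp;&nbsp;&nbsp;*D̂* = *a*·*S* − *b*·*S*<sub>1000</sub>,

fitted on untransformed counts with five-fold cross-validation and
pairs-bootstrap standard errors. The residual scatter σ<sub>r</sub> of
log₁₀ *D* about the model is then split into a measurement floor
σ<sub>m</sub> — the "minimum achievable error" (MAE), estimated as the
standard deviation of differences in log₁₀(*D*/*S*) between paired repeat
measurements — and intrinsic biological scatter

&nbsp;&nbsp;&nbsp;&nbsp;σ<sub>i</sub> = √(σ<sub>r</sub>² − σ<sub>m</sub>²),

all in dex (base-10 log units; 0.3 dex ≈ a factor of 2).

The package is aimed at immunologists and biostatisticians working with
AIRR-style rearrangement tables or per-subject clone/count tables. It
provides:

- **`tcrdiv.repertoire`** — reading/writing clone tables (AIRR or simple
  two-column TSV) and cohort tables; computing *S*, *D*, *S*<sub>k</sub>,
  *P*<sub>k</sub>.
- **`tcrdiv.simulate`** — a constructive synthetic-cohort generator that
  hits exact (*S*, *D*, *S*<sub>k</sub>) targets, with age/sex/CMV effects,
  multinomial sequencing subsampling and paired technical replicates.
- **`tcrdiv.stratified`** — decade-binned medians with percentile-bootstrap
  CIs, stratified and conditional curves, Spearman correlations.
- **`tcrdiv.models`** — the cross-validated linear model, an XGBoost
  regressor (default hyperparameters) for feature-importance analysis, and
  top-*k* sensitivity refits for k ∈ {10, 100, 1000}.
- **`tcrdiv.decompose`** — MAE estimation and the quadrature variance
  decomposition.
- **`tcrdiv.cli`** — a `tcrdiv` command with `simulate`, `metrics`,
  `curves`, `fit`, `decompose` and `analyze` subcommands, writing a
  manifest (config hash, seeds, version) with every run.

## Worked example

```python
import numpy as np
from tcrdiv import (SimulationParams, simulate_cohort, simulate_replicates,
                    fit_linear_model, decompose, spearman_correlation)

params = SimulationParams(n_subjects=10_000, seed=42)
cohort = simulate_cohort(params, materialize=False).metrics
print(f"median S = {cohort['S'].median():,.0f}   median D = {cohort['D'].median():,.0f}")

fit = fit_linear_model(cohort, n_boot=500, folds=5, seed=42)
print(f"D_hat = ({fit.a:.3f} +/- {fit.se_a:.3f}) * S - ({fit.b:.3f} +/- {fit.se_b:.3f}) * S_1000")
print(f"cross-validated R^2 = {fit.r2_cv:.3f}   residual sd = {fit.residual_sd_dex:.4f} dex")

reps = simulate_replicates(cohort, noise_sd=params.replicate_noise_sd, seed=42)
vd = decompose(fit, reps, log10_d=np.log10(cohort["D"]))
print(f"sigma_m (MAE) = {vd.sigma_m:.4f} dex   sigma_i = {vd.sigma_i:.4f} dex   "
      f"unexplained = {vd.fraction_unexplained:.1%}")

neg = cohort[cohort.cmv_status == "negative"]
rho, p = spearman_correlation(neg["S"], neg["P_1000"])
print(f"CMV-negative Spearman rho(S, P_1000) = {rho:.2f} (p = {p:.1e})")
```

prints

```
median S = 513,514   median D = 320,656
D_hat = (0.830 +/- 0.002) * S - (0.982 +/- 0.007) * S_1000
cross-validated R^2 = 0.964   residual sd = 0.0310 dex
sigma_m (MAE) = 0.0273 dex   sigma_i = 0.0148 dex   unexplained = 3.6%
CMV-negative Spearman rho(S, P_1000) = -0.25 (p = 3.1e-91)
```

Reading: the synthetic cohort is centred on a median repertoire of ~5×10⁵
templates and ~3.2×10⁵ clonotypes. The linear fit recovers the generative
coefficients, explains 96% of the variance in held-out diversity, and
leaves 0.031 dex of residual scatter; subtracting the 0.027 dex replicate
measurement floor in quadrature leaves 0.015 dex of intrinsic scatter —
only ~4% of diversity variability is unexplained by size and clonality.
The age-driven anticorrelation between size and clonal expansion among
CMV-negative subjects (ρ = −0.25) emerges without being targeted directly.

The same analysis runs from the shell on either a simulated cohort or a
real metrics table (columns `subject_id, age, sex, cmv_status, S, D, S_10,
S_100, S_1000`):

```bash
tcrdiv analyze --n 10000 --seed 42 --out results/run1
tcrdiv analyze --cohort my_cohort.csv --replicates my_replicates.csv --out results/run2
```

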