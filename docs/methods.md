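# Methods

## Data model

The universal input is a long ("tidy") yield table keyed by
`(dataset_id, source, treatment_id, environment_id, replicate)`, with
`source ∈ {observed, predicted}`. An *environment* is a year, or a
year-by-season compound label for double-cropping systems (the rice trial
runs a hot-dry and a wet season every year; the published stability table
treats each season's series separately, so the package follows the
year-by-season convention there). Missing values are explicit NA markers,
never zeros — zero is a valid crop-failure yield. Replicates are averaged
before any stability computation; the stability measures operate on
treatment-by-environment matrices of mean yields. All tabular I/O is
comma-delimited UTF-8 with a required header.

## Stability measures

**Adjusted CV.** The plain CV is confounded by the systematic dependence
of variance on mean (Taylor's power law). The package fits
`log₁₀(σ_i²) = a + b·log₁₀(Ȳ_i)` by OLS across the treatments of one
(dataset, source) group and computes

    aCV_i = (100 / Ȳ_i) · sqrt(10^( v_i + (2 − b)(m_i − m̄) ))

with `m_i = log₁₀ Ȳ_i`, `v_i = log₁₀ σ_i²`, `m̄` the group mean of the
`m_i`. Two exact identities pin the implementation down: at `b = 2` the
adjustment vanishes (aCV ≡ CV), and any treatment with `m_i = m̄` keeps
its plain CV regardless of `b`. Higher aCV = lower stability.

*Grouping policy.* The Taylor regression is fitted within each
(dataset, source) group, pooling all treatment levels of a crop; observed
and predicted series get separate fits. This matches the pooled "All"
comparisons of the reference agreement table. The grouping is a policy
choice, not derivable from the summaries themselves; recomputing the
published per-treatment aCVs from the *rounded* published means and SDs
reproduces them only to about one percentage point (e.g. 26.5 vs 27.1%
for the 0-N hot-dry-season rice cell), because the originals were
computed from unrounded yearly data.

**SYI.** `SYI_i = (Ȳ_i − SD_i) / Y_max` with `Y_max` the maximum yield
over all years and treatments of the series. `Y_max` is taken per
(dataset, source) — observed SYI is scaled by the observed maximum,
predicted SYI by the predicted one; back-solving the published rice SYI
values supports per-source maxima (≈8.4 observed vs ≈8.0 predicted).
When only summary moments are available, `Y_max` must be supplied
explicitly. SD is the sample (n−1) standard deviation throughout.

**Finlay–Wilkinson.** The environment index `ω_j` is the mean yield over
all treatments present in environment j; each treatment is regressed on
`ω_j` by unweighted OLS. On a complete matrix the slopes average exactly 1
(the regressor is the row-average of the responses), which the tests
assert to 1e−10. Slopes near 0 mark environment-insensitive treatments;
slopes above 1 amplify between-year differences. Treatments with fewer
than 3 non-missing environments are skipped with a warning. Zero-variance
treatments are excluded from the Taylor fit with a warning rather than
floored.

## Model evaluation

RMSE_a, RMSE_n = 100·RMSE_a/Ō, MAE, and Willmott's index
`WI = 1 − Σ(E−O)² / Σ(|E−Ō| + |O−Ō|)²` ∈ [0, 1]. MAE is by definition a
magnitude, so the signed mean bias `mean(E − O)` is reported separately
to recover the direction of model error. The regression block fits
predicted on observed (the scatter-plot convention). The mean comparison
is Welch's *unpaired* unequal-variance t-test with Welch–Satterthwaite
degrees of freedom; a paired option is exposed, since both conventions
appear in field-validation practice. When both series are constant and
equal, p = 1 by convention.

## Concordance

Lin's CCC uses population (1/n) moment estimators,
`CCC = 2s_xy / (s_x² + s_y² + (x̄ − ȳ)²)`, and decomposes exactly as
`CCC = r · Cb`. Cb is computed with the **signed** r, keeping Cb ∈ (0, 1]
for negative correlations. The published agreement table prints |r| (its
pearl-millet aCV row shows r = 0.32 beside CCC = −0.23 and Cb = 0.72,
consistent only with signed r = −0.315; a second subgroup cell confirms
this), so the package reports both signed r and |r|. Groups with n < 3
are flagged skipped. All 18 non-Finlay–Wilkinson published agreement
cells are recomputable from the bundled printed summaries at two-decimal
precision and are checked by `reproduce_report()`; the published F–W
agreement cells require the raw yearly yields, which are not published,
so the F–W concordance chain is exercised on synthetic panels instead.

## Sensitivity analysis

S_i and ST_i are the standard variance-based indices
`S_i = Var{E(f|x_i)}/Var{f}`, `ST_i = 1 − Var{E(f|x_−i)}/Var{f}`.
Designs come from the unscrambled Sobol' (LP-tau) sequence with the
all-zero first point skipped, so the first design point is the unit-cube
midpoint and a 400-point design over the bundled 7-parameter rice ranges
reproduces the reference experimental design shape. Index estimation uses
the Saltelli A/B/AB scheme with a seeded *scrambled* Sobol' base sample:
`S_i = mean(f_B·(f_AB_i − f_A))/V` and the Jansen total-effect estimator
`ST_i = mean((f_A − f_AB_i)²)/(2V)`, chosen for its lower variance. These
are Monte-Carlo estimators of the same estimands a Gaussian-process
emulator would target; direct estimation was chosen because the model
functions used here are cheap, which removes the emulator dependency and
its fitting uncertainty. Estimates are validated against closed forms
(additive model: S_i = ST_i = 1/3; Ishigami a=7, b=0.1: S1 = 0.3139,
S2 = 0.4424, S3 = 0, ST3 = 8b²π⁸/225/V ≈ 0.244) within ±0.02 at a base
sample of 8192; negative estimates are reported unclipped so estimator
bias stays visible. Failed model runs (None returns) remove their whole
design row-block (A, B and all AB_i rows) so the estimator matrices stay
paired; more than 50% failures aborts the analysis. Year-to-year index
distributions are summarised as Tukey boxplot statistics (median,
quartiles, 1.5·IQR whiskers clamped to the data, outlier count).

## Synthetic generators

**Yield panels.** `y_ij = β_i + α_i·ω_j + ε_ij` with
`ω_j ~ N(env_mean, env_sd²)` and `Var(ε_ij) = c·Ȳ_i^b`, so the panel has
exact Finlay–Wilkinson structure and a prescribed Taylor exponent. The
predicted series keeps each treatment's expected level, shrinks signal
and noise by a factor `s ∈ (0, 1]` and adds an independent noise draw
plus an optional bias — emulating the empirical pattern that model
predictions vary less between years than observations. Negative draws are
truncated at 0 (truncation logged; >10% escalates to an error in strict
mode); truncation keeps the moment structure analyzable — marginally each
yield is Gaussian truncated at zero, which the tests use as the exact
sampling-theory target for generated means.

**Presets.** `sadore_millet` (12 treatments × 8 seasons) and
`ndiaye_rice` (8 N-by-season cells × 8 years) take their treatment means
from the bundled published summaries; their Taylor (b, c) are fitted to
the published observed (mean, SD) pairs, so generated SDs follow the
empirical mean–variance scaling rather than matching each printed SD
cell. F–W slopes are set proportional to yield level (α_i = Ȳ_i/Ȳ̄), the
dominant empirical pattern. Environment SD, prediction shrinkage (0.9
millet, 0.45 rice) and bias (0, +0.3 Mg/ha) were chosen once to mirror
the two trials' observed-vs-predicted SD ratios. The rice preset uses a
complete 8-treatment × 8-environment layout with season as a treatment
factor; the real trial's wet-season series has 7 years, a simplification
that matters only for exact n bookkeeping.

What the generators do *not* emulate: spatial/block structure and
replicate-level error, serial correlation between years, management ×
year interactions beyond the linear F–W term, and any mechanistic
soil–water–N dynamics (the toy crop function is a smooth response
surface with one designed interaction and a thermal-time failure region,
not a process model). Tests passing on synthetic panels therefore
validate the *estimators*, not crop-model realism.

**Thermal time.** The Blackman increment `max(0, T − TBD)` for T below
the optimum TOD (defaults 15/34 °C). Behaviour at and above TOD is not
uniquely defined by the linear-below-optimum form; the default caps the
increment at `TOD − TBD` (linear-with-plateau), with a zero-above-optimum
switch for the alternative reading.

**Weather.** Sinusoidal seasonal temperature cycles plus Gaussian noise;
rainfall as a seasonally-weighted occurrence process with gamma
intensities whose mean is calibrated so the expected annual total matches
the station target (565 mm Sadoré, 277 mm Ndiaye); all draws from an
explicit seed.

## Numerical conventions and problem sizes

Sample (n−1) SD for all interannual summaries; population (1/n) moments
inside Lin's CCC (per its original definition); base-10 logs in the
Taylor fit; deterministic sort-based ordering of all outputs; every
stochastic routine takes an explicit seed and no global random state is
used. The test suite exercises Monte-Carlo checks at base samples of
1024–16384 for the sensitivity estimators, 200 environments for Taylor
exponent recovery, and 50 seeded replicates for the generator-level
distributional checks — sizes at which the documented tolerances (±0.02
on indices, ±0.1 on the Taylor exponent) hold with comfortable margin.

## Known limitations

- Stability recomputed from rounded summary moments can differ from
  values computed on raw yearly data by ~1 percentage point of aCV.
- The aCV grouping policy (which rows share one Taylor fit) changes
  results; it is configurable, and the pooled per-source default is a
  judgement call.
- The unpaired/paired t-test choice matters at small n; both are exposed.
- The concordance module reports point estimates only (no CIs).
- The LP-tau parity design is generated, but no Gaussian-process
  emulation is performed; per-year GP-emulator index values from other
  toolchains will differ by their emulator error.
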