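# Methods

This note documents the models behind `metaboprs`, the choices made where
several defensible conventions exist, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## The analysis model

The pipeline operates on a case-control cohort with one row per participant:
binary disease status, a precomputed standardized polygenic risk score
(PRS), a fixed panel of metabolite concentrations (168 by default, with a
27-member certified subset), and eighteen adjustment covariates.

**Probit scores.** Every metabolite enters models through the rank-based
inverse-normal transform `Φ⁻¹((rᵢ − ½)/m)` with average ranks on ties, where
m counts the non-missing entries of that column. This is the Blom-type
offset-½ convention common in epidemiology; it standardizes each biomarker's
range, removes skew, and is invariant to any strictly increasing rescaling
of the raw concentrations. Missing entries stay missing through the
transform; a constant column is an error because its ranks carry no
information.

**Imputation.** Single imputation: numeric columns take the median of their
observed values, factor and binary covariates the most frequent level with
ties broken by schema level order (determinism). Imputation is idempotent
and never alters observed cells. Nothing stronger than missing-completely-
at-random is assumed, matching the generator's missingness mechanism.

**Prediction tiers.** Four nested L1-penalized logistic regressions:
tier 1 metabolite probit columns only; tier 2 adds age, sex, ethnicity,
season, collection time and fasting hours; tier 3 adds smoking, alcohol,
caffeine, physical activity, BMI, systolic blood pressure, diabetes, HbA1c,
coronary artery disease, beta-blocker use, oral steroid use and spherical
equivalent; tier 4 adds the PRS. The data are split once, case-stratified,
into 80% training / 20% evaluation by a seeded shuffle. The penalty weight
is selected by 5-fold cross-validated deviance inside the training split
over 50 log-spaced weights (default grid 10⁻⁴…10⁴ on the inverse-penalty
scale), rule: minimum CV deviance, not 1-SE. The model is refit on the full
training split at the selected weight, and every reported AUC, confidence
interval and model comparison uses only the untouched 20%. The L1 penalty
zeroes coefficients, so the set of metabolites each model actually uses
shrinks with the penalty — the behaviour the tiered analysis relies on.

*Standardization.* Design columns are standardized to training-split
moments before penalized fitting and coefficients are reported back on the
original scale. An L1 penalty applied to raw scales weights predictors by
their units (mg/day of caffeine vs unit-variance probit scores), which is
statistically arbitrary and an order of magnitude slower for the coordinate-
descent solver; internal standardization is also what glmnet does by
default. No class weighting: the ~4% prevalence enters the likelihood
as-is.

**ROC/AUC and DeLong.** AUC is the tie-corrected Mann–Whitney statistic;
its variance and the paired two-curve test use DeLong's structural
components (midrank formulation). The implementation was cross-validated
against R `pROC`'s `roc.test(..., method="delong", paired=TRUE)`: AUCs, z
and p agree to ~10⁻¹⁵. Degenerate edge conventions: all-tied scores give
AUC ½ with zero variance; identical curves give p = 1.

**NEF correction.** For p correlated tests, the Bonferroni multiplier is
replaced by the number of eigenvalues of the p×p Pearson correlation matrix
(pairwise-complete observations) exceeding `variance_threshold` (default 1%)
of the total variance p; adjusted p-values are `min(1, p_raw · n_eff)`, and
n_eff is floored at 1. Pairwise-complete matrices need not be positive
semidefinite; negative eigenvalues cannot pass the threshold, and the
eigenvalue sum (the trace, = p) is preserved as reported. The correlation
matrix is computed from the same residual matrix whose columns are tested,
per stratum, so the correction reflects exactly the dependence structure of
the tested quantities.

**Resilience discovery.** Probit metabolites are residualized by ordinary
least squares on: age, age², fasting category (≤4 h reference / 5–8 h /
9+ h), sex, ethnicity, season, collection time, smoking, alcohol, caffeine,
activity, BMI, SBP, diabetes, HbA1c, CAD, beta-blocker, oral steroid and
spherical equivalent. (The source description of this step names a logistic
model, but residuals of a continuous metabolite can only come from a linear
model of the metabolite on its determinants; that is what is implemented.)
All 168 columns are solved in one SVD least-squares call with unit-norm
column scaling for conditioning; residuals are orthogonal to the design to
<10⁻⁸ and rank-deficient designs degrade gracefully to the minimum-norm
projection with a warning. The cohort is stratified at the 90th and 50th
empirical PRS percentiles (linear interpolation; ties kept high for the top
decile, low for the bottom half). Within a stratum, each metabolite's
residuals are compared between cases and non-cases with a two-sided Welch
t-test (robust to the very unequal group sizes); calls: NEF-adjusted
p < 0.05 significant, < 0.2 suggestive. A resilience metabolite has the
*higher* mean residual in unaffected participants.

**Metabolite risk score (MRS).** Unpenalized maximum-likelihood logistic
regression of status on all 168 probit metabolites, fit within each of five
seeded stratified folds; the exported weights are the element-wise mean of
the fold coefficient vectors. A non-converging fold falls back to a
negligible ridge (flagged). Scoring is a weighted sum of probit values
(intercept excluded) in two modes: `full_fit` applies the averaged betas to
everyone (what an in-sample analysis does); `out_of_fold` applies to each
participant the betas of the fold that held them out. The full-fit score is
optimistically correlated with status by construction — on null data it
manufactures an apparent main effect, which the test suite demonstrates —
so downstream inference defaults to out-of-fold scoring, with full-fit
retained for descriptive use.

**Interaction analyses.** The inferential test is the Wald test of the
continuous product term in `status ~ PRS + score + PRS·score + covariates`
(ML logistic; covariates = the residualization list above). The 16-cell
quartile cross-classification is descriptive: PRS and score are
independently quartiled (left-open/right-closed on the 25/50/75 empirical
percentiles), each cell gets a plain 2×2 odds ratio with a Wald 95% CI
against the declared reference — the same-PRS-quartile score-Q1 cell, or
the global (Q1, Q1) cell — with the Haldane–Anscombe +0.5 correction
flagged when a cell is empty. Reference cells carry OR exactly 1 and no
interval. Two odds ratios are compared by the 1-df chi-square on the
difference of log-ORs with independent-strata variances. The three-way age
modification test dichotomizes age at the stratum median (the study's cut
was 58 years) inside the top PRS decile and Wald-tests the
age×score×PRS product in a model holding all main effects, two-way
products and covariates.

## The synthetic cohort generator

The generator exists because participant-level biobank data of this shape
cannot be redistributed. It reproduces the *statistical structure* the
analyses assume, with defaults fixed at the study conditions:

* n = 117,698 participants, target prevalence 4% (intercept solved by
  monotone root-finding to ±10⁻⁶ on the realized linear predictors);
* PRS ~ N(0,1) with log-odds 0.8 per SD, giving a PRS-only AUC ≈
  Φ(0.8/√2) ≈ 0.71 — in the reported range for glaucoma PRS discrimination;
* 168 metabolites as exp(Z) over a latent Gaussian Z with nine equal
  correlation blocks, exchangeable within-block ρ = 0.9: the latent
  correlation matrix has nine leading eigenvalues capturing ≈90% of total
  variance, matching the reported eigen-structure of the real panel
  (9 components, 91.6%), and strong within-block correlation mirrors the
  near-duplicate lipoprotein sub-measures of NMR panels;
* a protective bilinear interaction γ·PRS·Zⱼ with γ = −0.15 on the
  lactate/pyruvate/citrate trio and no metabolite main effect (the study
  found no bottom-half association at the significant level);
* age confounding (0.07 log-odds/year, centered), all other covariates
  mutually independent with marginals loosely calibrated to the published
  Table-1-style characteristics;
* 2% missingness, completely at random, never on status or PRS.

Same seed, same table, byte for byte.

What it deliberately does **not** emulate: biobank sampling design and
consent structure; genotype-level variation (the PRS is a scalar); the true
Nightingale marginal distributions (log-normal is a stand-in, made
inconsequential downstream by the rank-based transform); informative
missingness; and any metabolite main effects or nonlinear dose-response.
Consequently, passing tests demonstrate that the *pipeline* recovers what
was planted under its assumed structure — not that the real-data effect
sizes or p-values would reproduce.

Two visible signatures of the bilinear interaction are worth knowing when
reading outputs. First, because the planted trio sits in a ρ = 0.9 block,
its block neighbours inherit most of the signal: discovery tables rank the
whole block together. Second, in the bottom PRS half the mean PRS is
negative, so the same metabolites score as *risk* factors there
(sign-reversed, much weaker); the quartile grid shows a rising OR gradient
in PRS Q1 mirroring the falling gradient in Q4.

## Numerical conventions

* Quartiles: linear-interpolation percentiles, label Q1 iff v ≤ c1, etc.;
  invariant to shifting and to row permutation.
* Mode imputation ties: first level in schema order.
* Logistic fits: statsmodels Newton (fallback L-BFGS) for unpenalized
  interaction models with convergence checked; sklearn liblinear for the
  penalized path (tol 10⁻⁶); sklearn lbfgs (tol 10⁻⁸, 500 iterations, tiny-
  ridge fallback) for MRS folds.
* CSV IO: `%.17g` on write and round-trip float parsing on read, so
  write→read is bit-exact; the empty string is the only missing-value code.
* Prevalence percentages: half-up rounding at one decimal.
* Seeds: every stochastic routine takes an explicit seed; derived seeds
  come from `numpy.random.SeedSequence`.

## Test and acceptance problem sizes

The simulation suites run at sizes chosen to estimate each operating
characteristic precisely while keeping the default test run in minutes:
DeLong null calibration at n = 500 (50 cases) with 10,000 replicates
(Monte-Carlo SE ≈ 0.002); interaction-test null calibration at n = 5,000
over 500 replicates; the NEF familywise guard on 50 exchangeably correlated
(ρ = 0.6) biomarkers in strata of 350 with 35 cases, 200 replicates;
planted-signal recovery at the study-like n = 100,000 over 25 replicates;
tier-nesting checks at n = 10,000 over 25 replicates with the penalty grid
spanning 10⁻⁴…10 (the selected weights sit well inside). The acceptance
script runs the full study-scale cohort (n = 117,698) for everything except
the prediction tiers, which use n = 20,000.

## Known limitations

* **NEF is anti-conservative.** The eigenvalue-threshold correction counts
  only components above 1% of total variance; dependence structure below
  that threshold still contributes independent test variation that the
  multiplier ignores. Measured on the 50-column exchangeable ρ = 0.6 null
  (stratum 350/35 cases): familywise error 0.078 ± 0.003 at nominal 0.05 —
  and it grows with stratum size (the sample eigen-bulk concentrates, the
  multiplier shrinks toward 1 while ~independent residual variation
  remains) and under partial within-block correlation (ρ = 0.9 blocks:
  ≈0.11–0.16). The acceptance guard bound of 0.08 therefore sits on the
  method's true value and a finite run lands on either side of it. Users
  needing strict familywise control should treat NEF calls as screening and
  confirm with permutation-based thresholds.
* The Wald CIs on cell odds ratios are unadjusted for covariates (the grid
  is descriptive); the adjusted inference is the continuous product term.
* Single imputation understates uncertainty from missingness; acceptable at
  2% MCAR, not for structured missingness.
* The penalty-selection rule (minimum CV deviance) can keep more columns
  than the 1-SE rule; flip by passing a custom grid or post-thresholding
  coefficients.
* With separation-prone tiny strata the unpenalized interaction models can
  fail to converge; the error is surfaced rather than silently regularized.
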