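# metaboprs

Metabolomic risk scores and polygenic-risk interaction analysis for
case-control biobank cohorts.

Glaucoma is strongly heritable, and a polygenic risk score (PRS) stratifies
risk well — yet many people in the top decile of genetic risk never develop
disease. This package implements the statistical pipeline used to ask two
questions of a cohort with NMR plasma metabolomics and a precomputed PRS:

1. **Do circulating metabolites improve disease prediction** beyond
   demographics, clinical covariates and the PRS? (Nested L1-penalized
   logistic models, held-out ROC/AUC, paired DeLong comparisons, stratified
   AUCs.)
2. **Is there a metabolomic signature of *resilience*** — metabolites whose
   adjusted levels are higher in unaffected individuals despite top-decile
   genetic risk — and does it statistically modify the PRS–disease
   relationship? (Covariate residualization, extreme-PRS stratification,
   per-metabolite Welch tests under an effective-number-of-tests correction,
   weighted metabolite risk scores, and 4×4 quartile odds-ratio grids.)

Real cohorts of this shape are access-restricted, so the package ships a
seeded synthetic-cohort generator that reproduces the statistical structure
the analyses assume (block-correlated log-normal metabolites, a calibrated
~4% prevalence, planted protective PRS×metabolite interactions, covariate
confounding, missingness). It is intended for methodologists and
epidemiologists who want a tested, reproducible implementation of this
analysis pattern, or a simulation harness to study its operating
characteristics.

## The statistics in brief

* **Probit scores.** Each biomarker is mapped through the rank-based
  inverse-normal transform `Φ⁻¹((rᵢ − ½)/m)` (average ranks on ties), giving
  standard-normal margins regardless of skew.
* **Prediction tiers.** `status ~ metabolites` (tier 1), `+ demographics`
  (tier 2), `+ lifestyle/comorbidity` (tier 3), `+ PRS` (tier 4), each as an
  L1-penalized logistic regression with the penalty chosen by 5-fold
  cross-validated deviance inside a seeded, case-stratified 80% training
  split; all AUCs are computed on the untouched 20% and compared with
  DeLong's structural-components test (implementation agrees with R `pROC`
  to machine precision).
* **NEF correction.** For p correlated tests, the Bonferroni multiplier is
  the number of eigenvalues of the biomarker correlation matrix
  (pairwise-complete Pearson) exceeding 1% of total variance:
  `p_NEF = min(1, p_raw · n_eff)`.
* **Resilience discovery.** Probit metabolites are OLS-residualized on the
  adjustment covariates (age, age², fasting category, sex, ethnicity,
  season, collection time, smoking, alcohol, caffeine, activity, BMI, SBP,
  diabetes, HbA1c, CAD, beta-blocker, oral steroid, spherical equivalent);
  Welch t-tests compare case vs non-case residuals inside the top PRS decile
  and bottom half, with NEF-adjusted calls at 0.05 (significant) and 0.2
  (suggestive).
* **Interaction.** `status ~ PRS + score + PRS·score + covariates`
  (maximum-likelihood logistic; Wald test of the product term), plus the
  descriptive 16-cell quartile cross-classification with 2×2 odds ratios
  against a declared reference cell, and a three-way age×score×PRS Wald test
  within the top decile.

## Worked example

```python
from metaboprs import (SimulationConfig, generate_cohort, impute,
                       probit_matrix, residualize, stratify_by_prs,
                       discover_resilience)

cohort = impute(generate_cohort(SimulationConfig(n_participants=60_000, seed=3)))
probit = probit_matrix(cohort)
residuals = residualize(probit, cohort)
top10, _ = stratify_by_prs(cohort)
hits = discover_resilience(residuals, cohort.status, top10, stratum="top10")
```

`examples/03_resilience_discovery.py` runs exactly this and prints
(top-decile excerpt):

```
top10: 761 cases / 5239 non-cases; NEF factor 9 (88.8% variance)
metabolite  mean_cases  mean_noncases     t    raw_p  adjusted_p_nef        call
   met_008      -0.619         0.0874 -18.7 5.47e-67        4.92e-66 significant
   met_004      -0.623         0.0833 -18.6 9.72e-67        8.75e-66 significant
   met_012       -0.61         0.0898 -18.5 5.79e-66        5.21e-65 significant
   met_016      -0.603         0.0873 -18.5 7.34e-66         6.6e-65 significant
   citrate       -0.61         0.0908 -18.4 1.65e-65        1.48e-64 significant
```

Reading: the correlated 168-metabolite panel collapses to 9 effective tests
capturing ~89% of its variance; the glycolysis/TCA trio planted as
protective — and, at within-block correlation 0.9, the rest of its
correlation block — shows significantly *higher* adjusted levels in
unaffected high-PRS participants: the resilience signature. The same trio
drives a negative PRS×score interaction (recovered at −0.145 against a
planted −0.15) and a falling odds-ratio gradient across metabolite-sum
quartiles inside the top PRS quartile — 1.0, 0.58, 0.40, 0.27 in
`examples/04_interaction_grid.py`.

Each script in `examples/` is a short, self-contained narrative of one
capability: cohort simulation and description, prediction tiers,
resilience discovery, and the interaction grid. A thin CLI wraps the same
pipeline (`metaboprs simulate|predict|resilience|interact|report|all`);
`metaboprs all --out runs/demo --seed 1` writes every stage artifact plus a
run manifest, and identical configurations reproduce identical artifacts.

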