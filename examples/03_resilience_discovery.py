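"""Discover metabolites tied to resilience against high genetic risk.

Probit metabolite scores are residualized on the adjustment covariates,
the cohort is stratified on the PRS (top decile vs bottom half), and each
metabolite's residuals are compared between cases and non-cases with a
Welch t-test under the number-of-effective-tests (NEF) correction.
"""

from metaboprs import (
    SimulationConfig,
    discover_resilience,
    generate_cohort,
    impute,
    probit_matrix,
    residualize,
    stratify_by_prs,
)

config = SimulationConfig(n_participants=60_000, seed=3)
cohort = impute(generate_cohort(config))
probit = probit_matrix(cohort)
residuals = residualize(probit, cohort)
top10, bottom50 = stratify_by_prs(cohort)

for name, rows in (("top10", top10), ("bottom50", bottom50)):
    result = discover_resilience(residuals, cohort.status, rows, stratum=name)
    print(f"\n{name}: {result.n_cases} cases / {result.n_noncases} non-cases; "
          f"NEF factor {result.nef.n_effective} "
          f"({100 * result.nef.variance_captured:.1f}% variance)")
    print(result.table.head(5).to_string(index=False,
                                         float_format=lambda v: f"{v:.3g}"))
# The planted protective trio (lactate, pyruvate, citrate) tops the
# top-decile table together with its correlation-block neighbours (at
# within-block rho=0.9 the block shares the signal), all with higher
# residuals in unaffected participants. The bottom half carries a weaker,
# sign-reversed trace of the same bilinear interaction (mean PRS is
# negative there), with adjusted p-values many orders of magnitude larger.
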