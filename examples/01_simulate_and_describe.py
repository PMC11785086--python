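"""Generate a synthetic case-control cohort and describe it.

The generator emulates a biobank-style glaucoma cohort: ~4% prevalence, a
standard-normal polygenic risk score (PRS) with a strong log-odds effect,
168 log-normal metabolites in nine correlated blocks, and a protective
PRS-by-metabolite interaction planted on lactate/pyruvate/citrate.
"""

from metaboprs import (
    SimulationConfig,
    generate_cohort,
    prevalence,
    stratify_by_prs,
    summarize_characteristics,
    write_cohort,
)

config = SimulationConfig(n_participants=20_000, seed=1)
cohort = generate_cohort(config)
write_cohort(cohort, "cohort_demo.csv")

n_cases = int(cohort.status.sum())
print(f"participants: {cohort.n}, cases: {n_cases}, "
      f"prevalence: {prevalence(n_cases, cohort.n - n_cases)}%")

top10, bottom50 = stratify_by_prs(cohort)
for name, rows in (("top PRS decile", top10), ("bottom PRS half", bottom50)):
    cases = int(cohort.status[rows].sum())
    print(f"{name}: n={len(rows)}, case rate {prevalence(cases, len(rows) - cases)}%")

summary = summarize_characteristics(cohort)
print("\nage by status (the generator plants age confounding):")
print(summary[summary.characteristic == "age"]
      [["cases_mean_sd", "noncases_mean_sd"]].to_string(index=False))
# Expect the case rate to be several-fold higher in the top PRS decile than
# in the bottom half, and cases to be older on average -- the structure the
# downstream analyses rely on.
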