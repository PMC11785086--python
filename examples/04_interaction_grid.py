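"""Quartile-stratified gene-by-metabolite interaction analysis.

Sums the probit scores of the resilience trio, tests the continuous
PRS-by-score interaction in a covariate-adjusted logistic model, and
cross-classifies PRS and score quartiles into a 16-cell odds-ratio grid
(reference: the lowest score quartile within each PRS quartile).
"""

from metaboprs import (
    SimulationConfig,
    build_interaction_table,
    generate_cohort,
    impute,
    probit_matrix,
    resilience_sum,
)

config = SimulationConfig(n_participants=60_000, seed=4)
cohort = impute(generate_cohort(config))
probit = probit_matrix(cohort)
score = resilience_sum(probit)

table = build_interaction_table(cohort, score, "within_prs_quartile")
print(f"interaction coefficient {table.interaction_coef:+.3f} per unit "
      f"PRS x score, Wald p = {table.interaction_p:.2g}")
print(f"(planted value: {config.gamma_interaction} per latent SD and PRS SD)\n")

grid = table.grid.pivot(index="prs_q", columns="score_q", values="or_value")
print("odds ratio vs score-Q1 within each PRS quartile:")
print(grid.round(2).to_string())
# With the protective interaction planted, odds ratios fall from left to
# right most steeply in the top PRS quartile -- high metabolite levels blunt
# the genetic risk gradient. The mirrored rise in the bottom PRS quartile is
# the signature of a bilinear PRS x metabolite term: where mean PRS is
# negative, the same metabolites score as risk factors.
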