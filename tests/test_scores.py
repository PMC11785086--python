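"""Metabolite risk scores and quartile-stratified interaction analyses."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from metaboprs import (
    CohortTable,
    ScoreVector,
    SimulationConfig,
    build_interaction_table,
    fit_mrs,
    generate_cohort,
    impute,
    interaction_test,
    odds_ratio_2x2,
    probit_matrix,
    resilience_sum,
    score_mrs,
    stratify_by_prs,
    three_way_age_interaction,
)

from conftest import make_probit_frame


class TestFitMRS:
    def test_planted_coefficient_recovered(self):
        rng = np.random.default_rng(51)
        probit = make_probit_frame(rng, 40_000, 10)
        z = probit.values.iloc[:, 3].to_numpy()
        y = (rng.random(40_000) < expit(-3.0 + 0.5 * z)).astype(int)
        model = fit_mrs(probit, y, seed=1)
        full = sm.Logit(y, sm.add_constant(probit.values.to_numpy())).fit(disp=0)
        np.testing.assert_allclose(model.betas.to_numpy(), full.params[1:], atol=0.05)
        assert model.betas.iloc[3] == pytest.approx(0.5, abs=0.1)
        others = model.betas.drop(model.betas.index[3])
        assert others.abs().max() < 0.1

    def test_null_betas_near_zero(self):
        rng = np.random.default_rng(52)
        probit = make_probit_frame(rng, 30_000, 8)
        y = (rng.random(30_000) < 0.05).astype(int)
        model = fit_mrs(probit, y, seed=2)
        assert model.betas.abs().max() < 0.12
        assert model.ridge_folds == ()

    def test_seed_only_changes_fold_assignment(self):
        rng = np.random.default_rng(53)
        probit = make_probit_frame(rng, 30_000, 6)
        y = (rng.random(30_000) < 0.08).astype(int)
        a = fit_mrs(probit, y, seed=3)
        b = fit_mrs(probit, y, seed=4)
        assert np.abs(a.betas.to_numpy() - b.betas.to_numpy()).max() < 0.05

    def test_single_class_rejected(self):
        probit = make_probit_frame(np.random.default_rng(54), 100, 3)
        with pytest.raises(ValueError):
            fit_mrs(probit, np.zeros(100, dtype=int), seed=0)


class TestScoreMRS:
    def test_zero_betas_zero_scores(self):
        rng = np.random.default_rng(55)
        probit = make_probit_frame(rng, 500, 4)
        y = (rng.random(500) < 0.3).astype(int)
        model = fit_mrs(probit, y, seed=5)
        model.betas[:] = 0.0
        assert (score_mrs(model, probit).to_numpy() == 0.0).all()

    def test_one_hot_beta_projects_column(self):
        rng = np.random.default_rng(56)
        probit = make_probit_frame(rng, 500, 4)
        y = (rng.random(500) < 0.3).astype(int)
        model = fit_mrs(probit, y, seed=6)
        model.betas[:] = 0.0
        model.betas.iloc[2] = 1.0
        np.testing.assert_allclose(score_mrs(model, probit).to_numpy(),
                                   probit.values.iloc[:, 2].to_numpy())

    def test_dot_product_oracle(self):
        rng = np.random.default_rng(57)
        probit = make_probit_frame(rng, 200, 5)
        y = (rng.random(200) < 0.4).astype(int)
        model = fit_mrs(probit, y, seed=7)
        expected = probit.values.to_numpy() @ model.betas.to_numpy()
        np.testing.assert_allclose(score_mrs(model, probit).to_numpy(), expected,
                                   atol=1e-12)

    def test_out_of_fold_uses_fold_betas(self):
        rng = np.random.default_rng(58)
        probit = make_probit_frame(rng, 1000, 4)
        y = (rng.random(1000) < 0.3).astype(int)
        model = fit_mrs(probit, y, seed=8)
        oof = score_mrs(model, probit, mode="out_of_fold").to_numpy()
        X = probit.values.to_numpy()
        B = model.fold_betas.to_numpy()
        manual = np.array([X[i] @ B[model.fold_assignment[i]] for i in range(1000)])
        np.testing.assert_allclose(oof, manual, atol=1e-12)

    def test_full_fit_score_is_optimistic_on_null_data(self):
        """In-sample weights manufacture an apparent score-status association."""
        rng = np.random.default_rng(59)
        probit = make_probit_frame(rng, 4000, 50)
        y = (rng.random(4000) < 0.1).astype(int)
        model = fit_mrs(probit, y, seed=9)
        z_stats = {}
        for mode in ("full_fit", "out_of_fold"):
            s = score_mrs(model, probit, mode=mode).to_numpy()
            fit = sm.Logit(y, sm.add_constant(np.column_stack([s]))).fit(disp=0)
            z_stats[mode] = abs(fit.tvalues[1])
        assert z_stats["full_fit"] > z_stats["out_of_fold"]
        assert z_stats["full_fit"] > 2.0  # overfitting bias is large by design

    def test_panel_mismatch_rejected(self):
        rng = np.random.default_rng(60)
        probit = make_probit_frame(rng, 300, 4)
        other = make_probit_frame(rng, 300, 5)
        y = (rng.random(300) < 0.3).astype(int)
        model = fit_mrs(probit, y, seed=10)
        with pytest.raises(ValueError):
            score_mrs(model, other)


class TestResilienceSum:
    def test_singleton_equals_column(self, probit_scores):
        s = resilience_sum(probit_scores, members=("lactate",))
        np.testing.assert_allclose(s.to_numpy(),
                                   probit_scores.values["lactate"].to_numpy())

    def test_mirrored_columns_cancel(self, probit_scores):
        values = probit_scores.values.copy()
        values["pyruvate"] = -values["lactate"]
        from metaboprs.preprocess import ProbitMatrix
        pm = ProbitMatrix(values=values, panel=probit_scores.panel,
                          n_nonmissing=values.notna().sum())
        s = resilience_sum(pm, members=("lactate", "pyruvate"))
        np.testing.assert_allclose(s.to_numpy(), 0.0, atol=1e-12)

    def test_three_column_sum_oracle(self, probit_scores):
        s = resilience_sum(probit_scores)
        expected = (probit_scores.values["lactate"]
                    + probit_scores.values["pyruvate"]
                    + probit_scores.values["citrate"])
        np.testing.assert_allclose(s.to_numpy(), expected.to_numpy(), atol=1e-12)

    def test_unknown_member_rejected(self, probit_scores):
        with pytest.raises(ValueError, match="not in panel"):
            resilience_sum(probit_scores, members=("unobtainium",))


@pytest.fixture(scope="module")
def planted_interaction():
    cfg = SimulationConfig(n_participants=30_000, n_metabolites=12, n_blocks=3,
                           gamma_interaction=-0.25, missing_rate=0.0, seed=61)
    table = impute(generate_cohort(cfg))
    probit = probit_matrix(table)
    return table, probit, resilience_sum(probit)


class TestInteraction:
    def test_planted_negative_interaction_detected(self, planted_interaction):
        table, _probit, score = planted_interaction
        p, coef = interaction_test(table, score)
        assert coef < 0.0
        assert p < 1e-4

    def test_degenerate_score_rejected(self, planted_interaction):
        table, _probit, score = planted_interaction
        zero = ScoreVector(values=pd.Series(np.zeros(table.n)),
                           kind="resilience_sum", provenance="full_fit")
        with pytest.raises(ValueError):
            interaction_test(table, zero)

    def test_protective_gradient_in_top_prs_quartile(self, planted_interaction):
        table, _probit, score = planted_interaction
        tab = build_interaction_table(table, score)
        q4 = {row["score_q"]: row for _, row in
              tab.grid[tab.grid.prs_q == "Q4"].iterrows()}
        assert q4["Q1"]["is_reference"] and q4["Q1"]["or_value"] == 1.0
        assert q4["Q4"]["or_value"] < q4["Q2"]["or_value"]
        assert q4["Q4"]["or_value"] < 1.0
        assert q4["Q4"]["ci_high"] < 1.0

    def test_grid_counts_conserve_cohort(self, planted_interaction):
        table, _probit, score = planted_interaction
        tab = build_interaction_table(table, score)
        assert tab.grid["n_total"].sum() == table.n
        assert tab.grid["n_cases"].sum() == table.status.sum()
        assert len(tab.grid) == 16

    def test_reference_cells_by_mode(self, planted_interaction):
        table, _probit, score = planted_interaction
        within = build_interaction_table(table, score, "within_prs_quartile")
        refs = within.grid[within.grid.is_reference]
        assert set(refs["score_q"]) == {"Q1"} and len(refs) == 4
        assert (refs["or_value"] == 1.0).all()
        global_ref = build_interaction_table(table, score, "global_q1q1")
        refs = global_ref.grid[global_ref.grid.is_reference]
        assert len(refs) == 1
        assert refs.iloc[0]["prs_q"] == "Q1" and refs.iloc[0]["score_q"] == "Q1"

    def test_hand_built_grid_matches_closed_form(self):
        """Fixed counts per cell reproduce the 2x2 odds-ratio arithmetic."""
        rng = np.random.default_rng(62)
        per_cell = 250
        cases = {("Q1", "Q1"): 10, ("Q1", "Q2"): 12, ("Q1", "Q3"): 9, ("Q1", "Q4"): 14,
                 ("Q2", "Q1"): 15, ("Q2", "Q2"): 11, ("Q2", "Q3"): 16, ("Q2", "Q4"): 13,
                 ("Q3", "Q1"): 20, ("Q3", "Q2"): 18, ("Q3", "Q3"): 12, ("Q3", "Q4"): 9,
                 ("Q4", "Q1"): 40, ("Q4", "Q2"): 30, ("Q4", "Q3"): 22, ("Q4", "Q4"): 15}
        prs, score_vals, status = [], [], []
        for qi, pq in enumerate(("Q1", "Q2", "Q3", "Q4")):
            for qj, sq in enumerate(("Q1", "Q2", "Q3", "Q4")):
                prs.extend(rng.uniform(qi + 0.01, qi + 0.99, per_cell))
                score_vals.extend(rng.uniform(qj + 0.01, qj + 0.99, per_cell))
                status.extend([1] * cases[(pq, sq)]
                              + [0] * (per_cell - cases[(pq, sq)]))
        cfg = SimulationConfig(n_participants=16 * per_cell, n_metabolites=3,
                               n_blocks=1, missing_rate=0.0, seed=63)
        base = generate_cohort(cfg)
        df = base.data.copy()
        df["prs"] = prs
        df["status"] = status
        table = CohortTable(df, base.panel)
        score = ScoreVector(values=pd.Series(score_vals, dtype=float),
                            kind="resilience_sum", provenance="full_fit")
        tab = build_interaction_table(table, score, "within_prs_quartile")
        for pq in ("Q1", "Q2", "Q3", "Q4"):
            ref_cases = cases[(pq, "Q1")]
            for sq in ("Q2", "Q3", "Q4"):
                cell = tab.cell(pq, sq)
                expected = odds_ratio_2x2(cases[(pq, sq)],
                                          per_cell - cases[(pq, sq)],
                                          ref_cases, per_cell - ref_cases)
                assert cell["or_value"] == pytest.approx(expected.or_value)
                assert cell["ci_low"] == pytest.approx(expected.ci_low)

    def test_three_way_interaction_runs_and_is_null(self, planted_interaction):
        table, _probit, score = planted_interaction
        top10, _ = stratify_by_prs(table)
        p, _coef = three_way_age_interaction(table, score, top10)
        assert 0.0 <= p <= 1.0

    def test_three_way_constant_age_rejected(self, planted_interaction):
        table, _probit, score = planted_interaction
        top10, _ = stratify_by_prs(table)
        df = table.data.copy()
        df["age"] = 60.0
        degenerate = CohortTable(df, table.panel)
        with pytest.raises(ValueError):
            three_way_age_interaction(degenerate, score, top10)

    def test_age_median_split_is_balanced(self, planted_interaction):
        table, _probit, score = planted_interaction
        top10, _ = stratify_by_prs(table)
        age = table.data["age"].to_numpy()[top10]
        cut = float(np.median(age))
        hi = (age >= cut).sum()
        assert abs(hi - len(top10) / 2) <= 1
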