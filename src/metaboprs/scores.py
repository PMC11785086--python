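"""Metabolite risk scores and gene-by-metabolite interaction analyses.

The metabolite risk score (MRS) is a weighted sum of probit metabolite
scores whose weights are logistic-regression coefficients estimated under
5-fold cross-validation: the exported model averages the fold coefficients,
and an out-of-fold scoring mode applies, to each participant, the
coefficients of the fold in which they were held out (unbiased for
downstream inference; the full-fit score is optimistically correlated with
status by construction).

Interactions are assessed two ways: the inferential test is the Wald test
on the continuous PRS-by-score product term of a covariate-adjusted
logistic model, and the descriptive view is a 4x4 quartile
cross-classification of PRS and score with per-cell odds ratios against a
declared reference cell. A three-way age modification test adds a binary
age split and all product terms within the top PRS decile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortTable
from .panel import RESILIENCE_TRIO
from .preprocess import (
    ProbitMatrix,
    QuartileAssignment,
    QUARTILE_LABELS,
    build_adjustment_design,
    quartile_bin,
)
from .stats import ORCell, odds_ratio_2x2


# ---------------------------------------------------------------------------
# metabolite risk score
# ---------------------------------------------------------------------------


@dataclass
class MRSModel:
    betas: pd.Series              # mean of fold coefficients, named by metabolite
    fold_betas: pd.DataFrame      # folds x metabolites
    fold_assignment: np.ndarray   # validation-fold id per fitting row
    folds: int
    seed: int
    ridge_folds: tuple[int, ...]  # folds where the ridge fallback was used


@dataclass
class ScoreVector:
    values: pd.Series
    kind: str          # "mrs" | "resilience_sum"
    provenance: str    # "out_of_fold" | "full_fit"

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def _fit_logit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Unpenalized ML logistic fit; tiny-ridge fallback on non-convergence."""
    est = LogisticRegression(penalty=None, solver="lbfgs", max_iter=500, tol=1e-8)
    est.fit(X, y)
    if est.n_iter_[0] < 500:
        return est.coef_[0].copy(), False
    ridge = LogisticRegression(penalty="l2", C=1e6, solver="lbfgs",
                               max_iter=1000, tol=1e-8)
    ridge.fit(X, y)
    return ridge.coef_[0].copy(), True


def fit_mrs(probit: ProbitMatrix, status: np.ndarray, folds: int = 5,
            seed: int = 0) -> MRSModel:
    """Cross-validated logistic coefficients over the full metabolite panel.

    Within each seeded stratified fold, an unpenalized logistic regression
    of status on all probit metabolite columns is fit on the training
    portion; the exported betas are the element-wise mean of the fold
    coefficient vectors. A fold that fails to converge falls back to a
    negligible ridge penalty and is flagged.
    """
    X = probit.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("probit matrix contains missing values; impute first")
    y = np.asarray(status)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_assignment = np.empty(len(y), dtype=np.int64)
    fold_betas = np.empty((folds, X.shape[1]))
    ridge_folds = []
    for f, (train, valid) in enumerate(kf.split(X, y)):
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"fold {f} lost a class; increase the cohort size")
        betas, used_ridge = _fit_logit(X[train], y[train])
        fold_betas[f] = betas
        fold_assignment[valid] = f
        if used_ridge:
            ridge_folds.append(f)

    names = list(probit.values.columns)
    return MRSModel(betas=pd.Series(fold_betas.mean(axis=0), index=names),
                    fold_betas=pd.DataFrame(fold_betas, columns=names),
                    fold_assignment=fold_assignment, folds=folds, seed=seed,
                    ridge_folds=tuple(ridge_folds))


def score_mrs(model: MRSModel, probit: ProbitMatrix,
              mode: str = "full_fit") -> ScoreVector:
    """Weighted sum of probit scores (intercept excluded).

    ``full_fit`` applies the averaged betas to everyone; ``out_of_fold``
    applies, per participant, the betas of the fold in which that
    participant was held out (requires the same rows the model was fit on).
    """
    if list(probit.values.columns) != list(model.betas.index):
        raise ValueError("probit panel does not match the MRS model")
    X = probit.values.to_numpy(dtype=float)
    if mode == "full_fit":
        values = X @ model.betas.to_numpy()
    elif mode == "out_of_fold":
        if len(probit.values) != len(model.fold_assignment):
            raise ValueError("out-of-fold scoring needs the fitting rows")
        B = model.fold_betas.to_numpy()
        values = np.einsum("ij,ij->i", X, B[model.fold_assignment])
    else:
        raise ValueError(f"unknown scoring mode {mode!r}")
    return ScoreVector(values=pd.Series(values, index=probit.values.index),
                       kind="mrs", provenance=mode)


def resilience_sum(probit: ProbitMatrix,
                   members: tuple[str, ...] = RESILIENCE_TRIO) -> ScoreVector:
    """Per-participant sum of the resilience metabolites' probit scores."""
    unknown = [m for m in members if m not in probit.values.columns]
    if unknown:
        raise ValueError(f"metabolites not in panel: {unknown}")
    values = probit.values[list(members)].sum(axis=1)
    return ScoreVector(values=values, kind="resilience_sum", provenance="full_fit")


# ---------------------------------------------------------------------------
# interaction models
# ---------------------------------------------------------------------------


def _fit_binomial(y: np.ndarray, X: pd.DataFrame):
    """ML logistic fit with rank and convergence diagnostics."""
    arr = X.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("design contains missing values")
    stds = arr.std(axis=0)
    degenerate = [c for c, s in zip(X.columns, stds) if c != "intercept" and s == 0.0]
    if degenerate:
        raise ValueError(f"degenerate (constant) design columns: {degenerate}")
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError("interaction design is rank-deficient")
    model = sm.Logit(y, arr)
    res = None
    err: Exception | None = None
    for method, maxiter in (("newton", 100), ("lbfgs", 3000)):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                candidate = model.fit(disp=0, method=method, maxiter=maxiter)
        except Exception as exc:  # noqa: BLE001 - surfaced with context
            err = exc
            continue
        if candidate.mle_retvals.get("converged", True):
            res = candidate
            break
    if res is None:
        raise RuntimeError(f"logistic fit did not converge: {err}")
    return res


def interaction_test(table: CohortTable, score: ScoreVector,
                     covariate_design: pd.DataFrame | None = None
                     ) -> tuple[float, float]:
    """Wald test of the continuous PRS-by-score product term.

    Fits ``status ~ PRS + score + PRS:score + covariates`` by maximum
    likelihood and returns ``(wald_p, coefficient)`` for the product term.
    The covariates default to the residualization adjustment set.
    """
    if covariate_design is None:
        covariate_design = build_adjustment_design(table)
    s = score.to_numpy()
    X = covariate_design.copy()
    X["prs"] = table.prs
    X["score"] = s
    X["prs_x_score"] = table.prs * s
    res = _fit_binomial(table.status, X)
    j = list(X.columns).index("prs_x_score")
    return float(res.pvalues[j]), float(res.params[j])


@dataclass
class InteractionTable:
    """Quartile cross-classified odds-ratio grid with its interaction test."""

    grid: pd.DataFrame           # one row per (prs_q, score_q) cell
    reference_mode: str          # "within_prs_quartile" | "global_q1q1"
    interaction_p: float
    interaction_coef: float
    prs_quartiles: QuartileAssignment
    score_quartiles: QuartileAssignment
    model_formula_note: str = (
        "interaction p from the continuous PRS x score product term of a "
        "covariate-adjusted logistic model; the quartile grid is descriptive")

    def cell(self, prs_q: str, score_q: str) -> pd.Series:
        m = (self.grid["prs_q"] == prs_q) & (self.grid["score_q"] == score_q)
        return self.grid[m].iloc[0]


def build_interaction_table(table: CohortTable, score: ScoreVector,
                            reference_mode: str = "within_prs_quartile",
                            covariate_design: pd.DataFrame | None = None
                            ) -> InteractionTable:
    """Cross-classify PRS and score quartiles into a 16-cell OR grid.

    ``within_prs_quartile`` compares each cell to the lowest score quartile
    of the same PRS quartile; ``global_q1q1`` compares every cell to the
    (PRS Q1, score Q1) cell. Reference cells carry OR exactly 1 with no
    interval. Cell ORs are unadjusted 2x2 odds ratios (Haldane-corrected
    when a cell is empty and flagged); the attached interaction p-value
    comes from the covariate-adjusted continuous product-term model.
    """
    if reference_mode not in ("within_prs_quartile", "global_q1q1"):
        raise ValueError(f"unknown reference mode {reference_mode!r}")
    prs_q = quartile_bin(table.prs, source="prs")
    score_q = quartile_bin(score.to_numpy(), source=score.kind)
    status = table.status

    counts: dict[tuple[str, str], tuple[int, int]] = {}
    for pq in QUARTILE_LABELS:
        for sq in QUARTILE_LABELS:
            m = prs_q.indicator(pq) & score_q.indicator(sq)
            counts[(pq, sq)] = (int(status[m].sum()), int(m.sum()))

    def reference_of(pq: str, sq: str) -> tuple[str, str]:
        return ("Q1", "Q1") if reference_mode == "global_q1q1" else (pq, "Q1")

    for pq in QUARTILE_LABELS:
        ref = reference_of(pq, "Q1")
        if counts[ref][0] < 1:
            raise ValueError(f"reference cell {ref} contains no cases")

    rows = []
    for pq in QUARTILE_LABELS:
        for sq in QUARTILE_LABELS:
            cases, total = counts[(pq, sq)]
            ref = reference_of(pq, sq)
            record = {"prs_q": pq, "score_q": sq, "n_cases": cases,
                      "n_total": total, "is_reference": (pq, sq) == ref}
            if (pq, sq) == ref:
                record.update({"or_value": 1.0, "ci_low": np.nan,
                               "ci_high": np.nan, "p": np.nan,
                               "corrected": False})
            else:
                ref_cases, ref_total = counts[ref]
                cell = odds_ratio_2x2(cases, total - cases,
                                      ref_cases, ref_total - ref_cases)
                record.update({"or_value": cell.or_value, "ci_low": cell.ci_low,
                               "ci_high": cell.ci_high, "p": cell.p,
                               "corrected": cell.corrected})
            rows.append(record)

    interaction_p, interaction_coef = interaction_test(
        table, score, covariate_design=covariate_design)
    return InteractionTable(grid=pd.DataFrame(rows), reference_mode=reference_mode,
                            interaction_p=interaction_p,
                            interaction_coef=interaction_coef,
                            prs_quartiles=prs_q, score_quartiles=score_q)


def three_way_age_interaction(table: CohortTable, score: ScoreVector,
                              stratum_rows: np.ndarray,
                              age_cut: float | None = None
                              ) -> tuple[float, float]:
    """Wald test of age x score x PRS modification in a high-PRS stratum.

    Age is dichotomized at ``age_cut`` (default: the stratum median age).
    The logistic model holds the three main effects, all two-way products,
    the three-way product, and the adjustment covariates; returns
    ``(wald_p, coefficient)`` for the three-way term.
    """
    stratum_rows = np.asarray(stratum_rows)
    sub_data = table.data.iloc[stratum_rows].reset_index(drop=True)
    sub = CohortTable(sub_data, table.panel)
    age = sub.data["age"].to_numpy(dtype=float)
    if age_cut is None:
        age_cut = float(np.median(age))
    age_hi = (age >= age_cut).astype(float)
    if age_hi.min() == age_hi.max():
        raise ValueError("age split is degenerate in this stratum")

    s = score.to_numpy()[stratum_rows]
    prs = sub.prs
    X = build_adjustment_design(sub)
    X["age_hi"] = age_hi
    X["score"] = s
    X["prs"] = prs
    X["age_hi_x_score"] = age_hi * s
    X["age_hi_x_prs"] = age_hi * prs
    X["score_x_prs"] = s * prs
    X["age_hi_x_score_x_prs"] = age_hi * s * prs
    res = _fit_binomial(sub.status, X)
    j = list(X.columns).index("age_hi_x_score_x_prs")
    return float(res.pvalues[j]), float(res.params[j])
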