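"""Resilience-metabolite discovery in extreme polygenic-risk strata.

Probit metabolite scores are residualized on a rich covariate set by
ordinary least squares, the cohort is stratified on the PRS distribution
(top decile vs bottom half), and each metabolite's residuals are compared
between cases and non-cases with Welch's t-test. Multiple testing is
corrected with the number-of-effective-tests (NEF) Bonferroni adjustment
computed from the stratum's residual correlation matrix. A "resilience"
metabolite shows higher adjusted levels in unaffected high-PRS individuals.

Residualization is linear (OLS) per metabolite: the covariate list given
for this step describes determinants of metabolite variability, so each
continuous probit score is regressed on it and the residuals are tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .preprocess import ProbitMatrix, build_adjustment_design
from .stats import NEFResult, nef_adjust, welch_t

SIGNIFICANT_THRESHOLD = 0.05
SUGGESTIVE_THRESHOLD = 0.2


@dataclass
class ResidualMatrix:
    """Covariate-adjusted probit scores: one residual column per metabolite."""

    residuals: pd.DataFrame
    covariate_list: list[str]
    r_squared: pd.Series

    @property
    def n(self) -> int:
        return len(self.residuals)


def residualize(probit: ProbitMatrix, table: CohortTable) -> ResidualMatrix:
    """OLS-residualize every probit metabolite column on the adjustment design.

    All columns are solved in one least-squares call; the design columns are
    rescaled to unit norm internally for conditioning (the fitted subspace,
    hence the residuals, are unchanged). Collinear design columns are
    tolerated: the minimum-norm solution still projects onto the column
    space, and a warning reports the rank deficiency.
    """
    design = build_adjustment_design(table)
    Y = probit.values.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("probit matrix contains missing values; impute first")
    X = design.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0.0] = 1.0
    Xs = X / norms
    beta, _res, rank, _sv = np.linalg.lstsq(Xs, Y, rcond=None)
    if rank < Xs.shape[1]:
        warnings.warn(f"adjustment design is rank-deficient "
                      f"(rank {rank} of {Xs.shape[1]}); collinear columns "
                      f"contribute nothing beyond the fitted subspace",
                      stacklevel=2)
    fitted = Xs @ beta
    residuals = Y - fitted
    total = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    explained = ((fitted - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(total > 0, explained / total, np.nan)
    return ResidualMatrix(
        residuals=pd.DataFrame(residuals, columns=probit.values.columns,
                               index=probit.values.index),
        covariate_list=[c for c in design.columns if c != "intercept"],
        r_squared=pd.Series(r2, index=probit.values.columns))


def stratify_by_prs(table: CohortTable) -> tuple[np.ndarray, np.ndarray]:
    """Split on the PRS distribution: top decile and bottom half.

    Returns positional row indices ``(top10, bottom50)``. The top stratum
    keeps ties at the 90th percentile on the high side and the bottom
    stratum keeps ties at the median on the low side; the two sets are
    disjoint by construction for any non-degenerate PRS.
    """
    prs = table.prs
    if len(prs) < 20:
        raise ValueError("need at least 20 participants to form PRS strata")
    q90 = np.percentile(prs, 90.0)
    q50 = np.percentile(prs, 50.0)
    top10 = np.flatnonzero(prs >= q90)
    bottom50 = np.flatnonzero(prs <= q50)
    if np.intersect1d(top10, bottom50).size:
        raise ValueError("degenerate PRS distribution: top-decile and "
                         "bottom-half strata overlap")
    return top10, bottom50


@dataclass
class ResilienceResult:
    """Per-metabolite stratum comparison with NEF-adjusted significance calls."""

    table: pd.DataFrame     # metabolite, mean_cases, mean_noncases, t, raw_p,
                            # adjusted_p_nef, call
    nef: NEFResult
    stratum: str
    n_cases: int
    n_noncases: int

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["call"] == "significant"]


def _call(p: float) -> str:
    if p < SIGNIFICANT_THRESHOLD:
        return "significant"
    if p < SUGGESTIVE_THRESHOLD:
        return "suggestive"
    return "null"


def discover_resilience(residuals: ResidualMatrix, status: np.ndarray,
                        stratum_rows: np.ndarray, stratum: str = "",
                        variance_threshold: float = 0.01,
                        min_per_class: int = 10) -> ResilienceResult:
    """Test every metabolite's residuals between cases and non-cases.

    Within the given stratum rows, each metabolite gets a two-sided Welch
    t-test of case vs non-case residual means; raw p-values are adjusted by
    the NEF factor computed from the *stratum's* residual correlation
    matrix, so the correction reflects the dependence of exactly the
    quantities tested. Calls: significant (< 0.05), suggestive (< 0.2),
    null.
    """
    status = np.asarray(status)
    sub = residuals.residuals.iloc[stratum_rows]
    y = status[stratum_rows].astype(bool)
    n_cases, n_noncases = int(y.sum()), int((~y).sum())
    if n_cases < min_per_class or n_noncases < min_per_class:
        raise ValueError(f"stratum needs >= {min_per_class} cases and non-cases "
                         f"(got {n_cases} / {n_noncases})")

    records = []
    raw_p = np.empty(sub.shape[1])
    for k, name in enumerate(sub.columns):
        col = sub[name].to_numpy(dtype=float)
        t, _df, p = welch_t(col[y], col[~y])
        raw_p[k] = p
        records.append({"metabolite": name,
                        "mean_cases": float(col[y].mean()),
                        "mean_noncases": float(col[~y].mean()),
                        "t": t, "raw_p": p})

    nef = nef_adjust(sub.to_numpy(dtype=float), raw_p,
                     variance_threshold=variance_threshold)
    out = pd.DataFrame(records)
    out["adjusted_p_nef"] = nef.adjusted_p
    out["call"] = [_call(p) for p in out["adjusted_p_nef"]]
    out = out.sort_values("adjusted_p_nef", kind="mergesort").reset_index(drop=True)
    return ResilienceResult(table=out, nef=nef, stratum=stratum,
                            n_cases=n_cases, n_noncases=n_noncases)
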