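"""Shared preprocessing: probit scores, imputation, quartiles, designs.

Metabolite concentrations are mapped to *probit scores* — a rank-based
inverse-normal transform that standardizes each biomarker's range and removes
skew — before entering any model. Missing covariates are filled with the
column median (numeric) or mode (factor), and categorical covariates are
dummy-coded against a declared reference level when design matrices are
built for the four nested prediction-model tiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .cohort import (
    COVARIATE_SCHEMA,
    TIER2_COVARIATES,
    TIER3_COVARIATES,
    CohortTable,
    Covariate,
    covariate_schema,
)
from .panel import MetabolitePanel

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


# ---------------------------------------------------------------------------
# probit transformation
# ---------------------------------------------------------------------------


def probit_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform of one biomarker column.

    Non-missing entries map to ``Phi^{-1}((rank - 0.5) / m)`` where ranks are
    averaged over ties and ``m`` counts the non-missing entries; missing
    entries stay missing. The transform is strictly monotone on distinct
    values, so it is invariant to any strictly increasing rescaling of the
    input.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = ~np.isnan(x)
    m = int(mask.sum())
    if np.unique(x[mask]).size < 2:
        raise ValueError("probit transform needs at least two distinct values")
    ranks = rankdata(x[mask], method="average")
    out[mask] = norm.ppf((ranks - 0.5) / m)
    return out


@dataclass
class ProbitMatrix:
    """Per-metabolite probit scores with their source panel."""

    values: pd.DataFrame
    panel: MetabolitePanel
    n_nonmissing: pd.Series

    @property
    def n(self) -> int:
        return len(self.values)


def probit_matrix(table: CohortTable) -> ProbitMatrix:
    """Probit-transform every metabolite column of a cohort."""
    cols = {}
    for name in table.panel.names:
        cols[name] = probit_transform(table.data[name].to_numpy(dtype=float))
    values = pd.DataFrame(cols, index=table.data.index)
    return ProbitMatrix(values=values, panel=table.panel,
                        n_nonmissing=values.notna().sum())


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def _mode_by_schema(series: pd.Series, levels: tuple[str, ...]) -> str:
    counts = series.dropna().value_counts()
    if counts.empty:
        raise ValueError(f"column {series.name!r} is fully missing")
    best = counts.max()
    for level in levels:  # schema order breaks ties deterministically
        if counts.get(level, 0) == best:
            return level
    return counts.idxmax()  # pragma: no cover - off-schema level


def impute(table: CohortTable) -> CohortTable:
    """Median/mode single imputation; idempotent, non-missing cells untouched.

    Numeric columns (metabolites and numeric covariates) are filled with the
    median of their non-missing entries; factor and binary covariates with
    the most frequent level, ties broken by schema level order.
    """
    df = table.data.copy()
    for name in table.panel.names:
        col = df[name]
        if col.isna().all():
            raise ValueError(f"metabolite {name!r} is fully missing")
        df[name] = col.fillna(col.median())
    for c in COVARIATE_SCHEMA:
        col = df[c.name]
        if col.isna().all():
            raise ValueError(f"covariate {c.name!r} is fully missing")
        if c.kind == "numeric":
            df[c.name] = col.fillna(col.median())
        elif c.kind == "binary":
            counts = col.dropna().astype(np.int64).value_counts()
            fill = 0 if counts.get(0, 0) >= counts.get(1, 0) else 1
            df[c.name] = col.fillna(fill).astype(np.int64)
        else:
            fill = _mode_by_schema(col, c.levels)
            df[c.name] = col.fillna(fill)
    return CohortTable(df, table.panel)


# ---------------------------------------------------------------------------
# quartile binning
# ---------------------------------------------------------------------------


@dataclass
class QuartileAssignment:
    """Quartile labels with the empirical cutpoints that produced them."""

    labels: np.ndarray  # "Q1".."Q4" per entry, None where input was missing
    cutpoints: tuple[float, float, float]
    source: str

    def indicator(self, label: str) -> np.ndarray:
        return self.labels == label


def quartile_bin(values, source: str = "") -> QuartileAssignment:
    """Assign empirical quartiles: Q1 if v <= c1, ... Q4 if v > c3.

    Cutpoints are the 25th/50th/75th percentiles (linear interpolation) of
    the non-missing values. Labels are invariant to adding a constant and to
    permuting the input rows.
    """
    x = np.asarray(values, dtype=float)
    mask = ~np.isnan(x)
    if mask.sum() < 4:
        raise ValueError("quartile binning needs at least four values")
    finite = x[mask]
    if np.unique(finite).size == 1:
        raise ValueError("quartiles undefined for a constant vector")
    c1, c2, c3 = np.percentile(finite, [25.0, 50.0, 75.0])
    labels = np.empty(x.shape, dtype=object)
    labels[~mask] = None
    labels[mask & (x <= c1)] = "Q1"
    labels[mask & (x > c1) & (x <= c2)] = "Q2"
    labels[mask & (x > c2) & (x <= c3)] = "Q3"
    labels[mask & (x > c3)] = "Q4"
    return QuartileAssignment(labels=labels, cutpoints=(float(c1), float(c2), float(c3)),
                              source=source)


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Named numeric design with intercept; factors dummy-coded vs reference."""

    frame: pd.DataFrame
    tier: int
    metabolite_set: str

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def to_numpy(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)


def _dummy_columns(series: pd.Series, cov: Covariate) -> dict[str, np.ndarray]:
    cols = {}
    for level in cov.levels[1:]:  # first level is the reference
        cols[f"{cov.name}[{level}]"] = (series == level).to_numpy(dtype=float)
    return cols


def _covariate_columns(table: CohortTable, names: tuple[str, ...]) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    for name in names:
        cov = covariate_schema(name)
        series = table.data[name]
        if cov.kind == "factor":
            cols.update(_dummy_columns(series, cov))
        else:
            cols[name] = series.to_numpy(dtype=float)
    return cols


def build_design(table: CohortTable, tier: int, metabolite_set: str,
                 probit: ProbitMatrix | None = None) -> DesignMatrix:
    """Assemble the design matrix for one prediction-model tier.

    Tier 1 holds probit metabolite columns only; tier 2 adds demographics
    (age, sex, ethnicity, season, collection time, fasting hours); tier 3
    adds lifestyle and comorbidity covariates; tier 4 adds the PRS. The
    table must already be imputed. ``probit`` may supply precomputed probit
    scores to avoid re-transforming.
    """
    if tier not in (1, 2, 3, 4):
        raise ValueError("tier must be 1..4")
    met_names = table.panel.subset_names(metabolite_set)
    if tier == 1 and not met_names:
        raise ValueError("tier 1 with no metabolites is an empty design")

    cols: dict[str, np.ndarray] = {"intercept": np.ones(table.n)}
    if met_names:
        if probit is None:
            probit = probit_matrix(table)
        for name in met_names:
            cols[name] = probit.values[name].to_numpy(dtype=float)
    if tier >= 2:
        cols.update(_covariate_columns(table, TIER2_COVARIATES))
    if tier >= 3:
        cols.update(_covariate_columns(table, TIER3_COVARIATES))
    if tier >= 4:
        cols["prs"] = table.prs

    frame = pd.DataFrame(cols, index=table.data.index)
    if frame.isna().any().any():
        raise ValueError("design contains missing values; impute the table first")
    return DesignMatrix(frame=frame, tier=tier, metabolite_set=metabolite_set)


FASTING_CATEGORY_LABELS = ("fasting[5-8h]", "fasting[9+h]")  # reference: <=4 h


def build_adjustment_design(table: CohortTable) -> pd.DataFrame:
    """Covariate design used for metabolite residualization and interactions.

    Age enters linearly and squared; fasting time as categories <=4 h
    (reference), 5-8 h, 9+ h; all other adjustment covariates as in tier 3.
    Returns a full-rank numeric frame with an intercept column.
    """
    age = table.data["age"].to_numpy(dtype=float)
    fasting = table.data["fasting_hours"].to_numpy(dtype=float)
    if np.isnan(age).any() or np.isnan(fasting).any():
        raise ValueError("impute the table before building the adjustment design")
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(table.n),
        "age": age,
        "age_sq": age ** 2,
        "fasting[5-8h]": ((fasting > 4.0) & (fasting <= 8.0)).astype(float),
        "fasting[9+h]": (fasting > 8.0).astype(float),
    }
    for name in ("sex", "ethnicity", "season", "collection_time", "smoking"):
        cols.update(_covariate_columns(table, (name,)))
    for name in ("alcohol", "caffeine", "activity", "bmi", "sbp", "diabetes",
                 "hba1c", "cad", "beta_blocker", "oral_steroid", "sph_eq"):
        cols[name] = table.data[name].to_numpy(dtype=float)
    frame = pd.DataFrame(cols, index=table.data.index)
    if frame.isna().any().any():
        raise ValueError("adjustment design contains missing values")
    return frame
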