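"""Descriptive bookkeeping: prevalence and cohort characteristic summaries."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import COVARIATE_SCHEMA, CohortTable
from .stats import welch_t


def _round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def prevalence(n_cases: int, n_noncases: int) -> float:
    """Percent prevalence, half-up rounded to one decimal place."""
    if n_cases < 0 or n_noncases < 0:
        raise ValueError("counts must be non-negative")
    total = n_cases + n_noncases
    if total == 0:
        raise ValueError("total count must be positive")
    return _round_half_up(100.0 * n_cases / total, 1)


@dataclass
class StratumSummary:
    stratum_name: str
    n_cases: int
    n_noncases: int

    @property
    def prevalence_pct(self) -> float:
        return prevalence(self.n_cases, self.n_noncases)


def stratum_summary(table: CohortTable, rows: np.ndarray, name: str) -> StratumSummary:
    status = table.status[np.asarray(rows)]
    return StratumSummary(stratum_name=name, n_cases=int(status.sum()),
                          n_noncases=int(len(status) - status.sum()))


def _numeric_rows(name: str, by_group: dict[str, pd.Series],
                  include_tests: bool) -> list[dict]:
    row = {"characteristic": name, "level": "", "type": "numeric"}
    for g, col in by_group.items():
        x = col.dropna().to_numpy(dtype=float)
        q1, med, q3 = np.percentile(x, [25, 50, 75]) if len(x) else (np.nan,) * 3
        row[f"{g}_mean_sd"] = f"{x.mean():.2f} ({x.std(ddof=1):.2f})" if len(x) > 1 else ""
        row[f"{g}_median_iqr"] = f"{med:.2f} [{q1:.2f}, {q3:.2f}]" if len(x) else ""
        row[f"{g}_n_missing"] = int(col.isna().sum())
    if include_tests:
        a = by_group["cases"].dropna()
        b = by_group["noncases"].dropna()
        try:
            _t, _df, p = welch_t(a, b)
            row["p_value"] = p
        except ValueError:
            row["p_value"] = np.nan
    return [row]


def _factor_rows(name: str, levels: tuple[str, ...], by_group: dict[str, pd.Series],
                 include_tests: bool) -> list[dict]:
    rows = []
    counts = {g: col.value_counts() for g, col in by_group.items()}
    totals = {g: int(col.notna().sum()) for g, col in by_group.items()}
    for level in levels:
        row = {"characteristic": name, "level": str(level), "type": "factor"}
        for g in by_group:
            k = int(counts[g].get(level, 0))
            pct = 100.0 * k / totals[g] if totals[g] else np.nan
            row[f"{g}_n_pct"] = f"{k} ({pct:.1f})"
            row[f"{g}_n_missing"] = int(by_group[g].isna().sum())
        rows.append(row)
    if include_tests and rows:
        tab = np.array([[counts[g].get(level, 0) for level in levels]
                        for g in by_group])
        keep = tab.sum(axis=0) > 0
        try:
            _c, p, _df, _e = sps.chi2_contingency(tab[:, keep])
        except ValueError:
            p = np.nan
        rows[0]["p_value"] = p
    return rows


def summarize_characteristics(table: CohortTable,
                              include_tests: bool = False) -> pd.DataFrame:
    """Case/non-case characteristic table on observed (unimputed) values.

    Numeric covariates report mean (SD) and median [IQR]; factors report
    level counts with column percentages inside each group. Group-difference
    tests (Welch t / chi-square) are attached only when ``include_tests``
    is set.
    """
    is_case = table.status == 1
    rows: list[dict] = [{
        "characteristic": "sample_size", "level": "", "type": "count",
        "cases_n_pct": f"{int(is_case.sum())} "
                       f"({prevalence(int(is_case.sum()), int((~is_case).sum()))})",
        "noncases_n_pct": f"{int((~is_case).sum())} "
                          f"({_round_half_up(100 - 100 * is_case.mean(), 1)})",
    }]
    groups = {"noncases": ~is_case, "cases": is_case}
    for cov in COVARIATE_SCHEMA:
        by_group = {g: table.data.loc[m, cov.name] for g, m in groups.items()}
        if cov.kind == "numeric":
            rows.extend(_numeric_rows(cov.name, by_group, include_tests))
        elif cov.kind == "binary":
            as_str = {g: s.map(lambda v: str(int(v)), na_action="ignore")
                      for g, s in by_group.items()}
            rows.extend(_factor_rows(cov.name, ("0", "1"), as_str, include_tests))
        else:
            rows.extend(_factor_rows(cov.name, cov.levels, by_group, include_tests))
    return pd.DataFrame(rows)
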