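"""Self-contained statistical primitives.

* Mann-Whitney AUC with DeLong structural-component variance and the paired
  DeLong test for two correlated ROC curves,
* the number-of-effective-tests (NEF) multiple-testing correction: a
  Bonferroni adjustment whose test count is the number of eigen components
  of the biomarker correlation matrix exceeding a variance-fraction
  threshold,
* two-by-two odds ratios with Wald confidence intervals (Haldane-Anscombe
  corrected when a cell is empty) and a 1-df chi-square comparison of two
  independent odds ratios,
* Welch's unequal-variance t-test.

Everything here is pure computation on arrays; results serialize to JSON.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

Z_95 = 1.959964  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# AUC / DeLong
# ---------------------------------------------------------------------------


@dataclass
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    variance: float

    def to_dict(self) -> dict:
        return asdict(self)


def _check_binary_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be coded 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels.astype(bool)


def _delong_components(scores: np.ndarray, pos_mask: np.ndarray):
    """AUC plus per-subject structural components (Sun & Xu midrank form)."""
    pos = scores[pos_mask]
    neg = scores[~pos_mask]
    m, n = len(pos), len(neg)
    tx = rankdata(pos, method="average")
    ty = rankdata(neg, method="average")
    tz = rankdata(np.concatenate([pos, neg]), method="average")
    v01 = (tz[:m] - tx) / n            # one component per case
    v10 = 1.0 - (tz[m:] - ty) / m      # one component per non-case
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    return float(auc), v01, v10


def auc_mann_whitney(scores, labels) -> AUCResult:
    """AUC as the scaled Mann-Whitney statistic, ties counted one half.

    The variance is DeLong's structural-components estimator; the 95% CI is
    Wald on the AUC scale, clipped to [0, 1]. With every score identical the
    AUC is exactly 0.5 with zero variance.
    """
    scores = np.asarray(scores, dtype=float)
    pos_mask = _check_binary_labels(labels)
    if scores.shape != pos_mask.shape:
        raise ValueError("scores and labels differ in length")
    auc, v01, v10 = _delong_components(scores, pos_mask)
    m, n = len(v01), len(v10)
    var = 0.0
    if m > 1 and n > 1:
        var = float(np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n)
    half = Z_95 * math.sqrt(max(var, 0.0))
    return AUCResult(auc=auc, ci_low=max(0.0, auc - half), ci_high=min(1.0, auc + half),
                     n_pos=m, n_neg=n, variance=var)


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float, float]:
    """Paired DeLong test for two correlated ROC curves on the same subjects.

    Returns ``(auc_a, auc_b, z, p)`` with ``z = (auc_a - auc_b) / sd`` where
    the standard deviation accounts for the covariance of the two curves'
    structural components. Antisymmetric under swapping the two score
    vectors. Identical curves give z = 0, p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors differ in length")
    pos_mask = _check_binary_labels(labels)
    if a.shape != pos_mask.shape:
        raise ValueError("scores and labels differ in length")

    auc_a, v01_a, v10_a = _delong_components(a, pos_mask)
    auc_b, v01_b, v10_b = _delong_components(b, pos_mask)
    m, n = len(v01_a), len(v10_a)
    d01 = v01_a - v01_b
    d10 = v10_a - v10_b
    var_diff = 0.0
    if m > 1 and n > 1:
        var_diff = float(np.var(d01, ddof=1) / m + np.var(d10, ddof=1) / n)
    delta = auc_a - auc_b
    if var_diff <= 0.0:
        if abs(delta) < 1e-15:
            return auc_a, auc_b, 0.0, 1.0
        z = math.inf if delta > 0 else -math.inf
        return auc_a, auc_b, z, 0.0
    z = delta / math.sqrt(var_diff)
    p = 2.0 * sps.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


# ---------------------------------------------------------------------------
# number of effective tests
# ---------------------------------------------------------------------------


@dataclass
class NEFResult:
    eigenvalues: np.ndarray        # nonincreasing; sums to p (trace of corr)
    n_effective: int
    variance_captured: float
    raw_p: np.ndarray
    adjusted_p: np.ndarray

    def to_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "n_effective": self.n_effective,
            "variance_captured": self.variance_captured,
            "raw_p": self.raw_p.tolist(),
            "adjusted_p": self.adjusted_p.tolist(),
        }


def nef_adjust(data_matrix, raw_p, variance_threshold: float = 0.01) -> NEFResult:
    """Effective-number-of-tests Bonferroni correction.

    A Pearson correlation matrix is computed over pairwise-complete
    observations of ``data_matrix`` (n x p, NaN = missing), its eigenvalues
    are extracted, and the effective test count is the number of components
    whose eigenvalue exceeds ``variance_threshold`` of the total variance
    ``p`` (at least one). Adjusted p-values are ``min(1, raw_p * n_eff)``.

    Pairwise-complete correlation matrices need not be positive
    semidefinite; negative eigenvalues cannot pass the threshold and are
    irrelevant to the count.
    """
    X = pd.DataFrame(np.asarray(data_matrix, dtype=float))
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least two columns")
    raw_p = np.asarray(raw_p, dtype=float)
    if raw_p.shape != (p,):
        raise ValueError("raw_p length must equal the number of columns")
    variances = X.var(ddof=1)
    if (variances <= 0).any() or variances.isna().any():
        raise ValueError("every column must have positive variance")
    corr = X.corr(method="pearson", min_periods=2)
    if corr.isna().any().any():
        raise ValueError("a column pair lacks two complete observations "
                         "or has undefined correlation")
    eigenvalues = np.linalg.eigvalsh(corr.to_numpy())[::-1]
    passing = eigenvalues > variance_threshold * p
    n_effective = max(1, int(passing.sum()))
    if passing.any():
        variance_captured = float(eigenvalues[passing].sum() / p)
    else:  # degenerate: fall back to the leading component
        variance_captured = float(eigenvalues[0] / p)
    adjusted = np.minimum(1.0, raw_p * n_effective)
    return NEFResult(eigenvalues=eigenvalues, n_effective=n_effective,
                     variance_captured=variance_captured, raw_p=raw_p,
                     adjusted_p=adjusted)


# ---------------------------------------------------------------------------
# odds ratios
# ---------------------------------------------------------------------------


@dataclass
class ORCell:
    """2x2 odds ratio with Wald CI on the log scale.

    ``counts`` is (cases_exposed, noncases_exposed, cases_ref, noncases_ref).
    ``corrected`` flags the Haldane-Anscombe +0.5 continuity correction
    applied when any cell is zero.
    """

    or_value: float
    ci_low: float
    ci_high: float
    p: float
    counts: tuple[int, int, int, int]
    log_or_se: float
    corrected: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> ORCell:
    """Odds ratio (a*d)/(b*c) with 95% Wald CI and two-sided Wald p."""
    counts = (int(a), int(b), int(c), int(d))
    if min(counts) < 0:
        raise ValueError("counts must be non-negative")
    corrected = 0 in counts
    aa, bb, cc, dd = ((x + 0.5 for x in counts) if corrected else counts)
    or_value = (aa * dd) / (bb * cc)
    log_or = math.log(or_value)
    se = math.sqrt(1.0 / aa + 1.0 / bb + 1.0 / cc + 1.0 / dd)
    z = log_or / se
    p = 2.0 * sps.norm.sf(abs(z))
    return ORCell(or_value=float(or_value),
                  ci_low=float(math.exp(log_or - Z_95 * se)),
                  ci_high=float(math.exp(log_or + Z_95 * se)),
                  p=float(p), counts=counts, log_or_se=float(se),
                  corrected=corrected)


def compare_odds_ratios(cell_a: ORCell, cell_b: ORCell) -> tuple[float, float]:
    """1-df chi-square comparison of two independent-strata odds ratios.

    The statistic is the squared Wald z of the log-OR difference with
    independent variances; returns ``(chi2, p)``.
    """
    diff = math.log(cell_a.or_value) - math.log(cell_b.or_value)
    var = cell_a.log_or_se ** 2 + cell_b.log_or_se ** 2
    chi2 = diff * diff / var
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Welch t-test
# ---------------------------------------------------------------------------


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch unequal-variance t-test; returns (t, Satterthwaite df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    if np.var(x, ddof=1) <= 0 or np.var(y, ddof=1) <= 0:
        raise ValueError("each group needs positive variance")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
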