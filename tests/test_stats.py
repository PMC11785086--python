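"""Statistical kernels: AUC/DeLong, NEF correction, odds ratios, Welch t."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from metaboprs import (
    auc_mann_whitney,
    compare_odds_ratios,
    delong_test,
    nef_adjust,
    odds_ratio_2x2,
    welch_t,
)


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if s > t else (0.5 if s == t else 0.0) for s in pos for t in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        res = auc_mann_whitney([0, 0, 1, 1], [0, 0, 1, 1])
        assert res.auc == 1.0

    def test_all_ties_give_half(self):
        res = auc_mann_whitney([3.0] * 10, [0] * 5 + [1] * 5)
        assert res.auc == 0.5
        assert res.variance == 0.0

    def test_pairwise_counting_example(self):
        res = auc_mann_whitney([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert res.auc == 0.75  # 3 wins, 1 loss over the 4 case/non-case pairs

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(8, 40))
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            res = auc_mann_whitney(scores, labels)
            assert res.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_negation_symmetry_exact(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=100)
        labels = (rng.random(100) < 0.3).astype(int)
        a = auc_mann_whitney(scores, labels).auc
        b = auc_mann_whitney(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(2)
        labels = (rng.random(300) < 0.2).astype(int)
        scores = labels + rng.normal(0, 1.5, 300)
        res = auc_mann_whitney(scores, labels)
        assert res.ci_low <= res.auc <= res.ci_high
        assert res.variance > 0

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auc_mann_whitney([1.0, 2.0], [1, 1])


class TestDeLong:
    def test_identical_curves(self):
        rng = np.random.default_rng(3)
        labels = np.array([0] * 30 + [1] * 10)
        scores = rng.normal(size=40)
        _a, _b, z, p = delong_test(scores, scores, labels)
        assert z == 0.0 and p == 1.0

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(4)
        labels = (rng.random(200) < 0.25).astype(int)
        a = labels + rng.normal(0, 2, 200)
        b = rng.normal(size=200)
        _, _, z_ab, p_ab = delong_test(a, b, labels)
        _, _, z_ba, p_ba = delong_test(b, a, labels)
        assert z_ab == pytest.approx(-z_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            delong_test([1.0, 2.0], [1.0], [0, 1])

    def test_agrees_with_stratified_bootstrap(self):
        """Informative vs noise score: both routes call it the same way."""
        rng = np.random.default_rng(5)
        n = 2000
        labels = (rng.random(n) < 0.15).astype(int)
        informative = labels * 0.8 + rng.normal(0, 1, n)
        noise = rng.normal(size=n)
        _, _, _, p = delong_test(informative, noise, labels)

        pos = np.flatnonzero(labels == 1)
        neg = np.flatnonzero(labels == 0)
        diffs = []
        for _ in range(2000):
            idx = np.concatenate([rng.choice(pos, len(pos)), rng.choice(neg, len(neg))])
            lab = labels[idx]
            diffs.append(auc_mann_whitney(informative[idx], lab).auc
                         - auc_mann_whitney(noise[idx], lab).auc)
        diffs = np.asarray(diffs)
        boot_p = 2.0 * min((diffs <= 0).mean(), (diffs >= 0).mean())
        assert (p < 0.01 and boot_p < 0.01) or (p > 0.10 and boot_p > 0.10)


def jacobi_eigenvalues(matrix, sweeps=60):
    """Independent symmetric eigensolver (cyclic Jacobi rotations)."""
    A = np.array(matrix, dtype=float, copy=True)
    n = A.shape[0]
    for _ in range(sweeps):
        off = np.sum(np.tril(A, -1) ** 2)
        if off < 1e-24:
            break
        for p in range(n - 1):
            for q in range(p + 1, n):
                if abs(A[p, q]) < 1e-18:
                    continue
                theta = 0.5 * math.atan2(2.0 * A[p, q], A[q, q] - A[p, p])
                c, s = math.cos(theta), math.sin(theta)
                rot_p = c * A[:, p] - s * A[:, q]
                rot_q = s * A[:, p] + c * A[:, q]
                A[:, p], A[:, q] = rot_p, rot_q
                rot_p = c * A[p, :] - s * A[q, :]
                rot_q = s * A[p, :] + c * A[q, :]
                A[p, :], A[q, :] = rot_p, rot_q
    return np.sort(np.diag(A))[::-1]


class TestNEF:
    def test_identity_correlation_is_plain_bonferroni(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((2000, 10))
        raw = np.linspace(0.001, 0.1, 10)
        res = nef_adjust(X, raw)
        assert res.n_effective == 10
        np.testing.assert_allclose(res.adjusted_p, np.minimum(1.0, raw * 10))

    def test_rank_one_gives_single_test(self):
        x = np.random.default_rng(7).standard_normal(500)
        X = np.column_stack([x] * 5)
        raw = np.full(5, 0.03)
        res = nef_adjust(X, raw)
        assert res.n_effective == 1
        np.testing.assert_allclose(res.adjusted_p, raw)
        np.testing.assert_allclose(res.eigenvalues, [5, 0, 0, 0, 0], atol=1e-10)

    def test_eigenvalue_sum_equals_trace(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((300, 12)) @ rng.standard_normal((12, 12))
        res = nef_adjust(X, np.full(12, 0.5))
        assert res.eigenvalues.sum() == pytest.approx(12.0, abs=1e-8)
        assert 1 <= res.n_effective <= 12
        assert 0 < res.variance_captured <= 1.0 + 1e-12

    def test_matches_independent_jacobi_solver(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((400, 8))
        X[:, 4:] += 2.0 * X[:, :4]  # induce structure
        res = nef_adjust(X, np.full(8, 0.5))
        corr = np.corrcoef(X, rowvar=False)
        oracle = jacobi_eigenvalues(corr)
        np.testing.assert_allclose(res.eigenvalues, oracle, atol=1e-8)
        assert res.n_effective == int(np.sum(oracle / 8 > 0.01))

    def test_monotone_in_exchangeable_correlation(self):
        rng = np.random.default_rng(10)
        n, p = 3000, 20
        previous = p + 1
        for rho in (0.0, 0.3, 0.6, 0.9):
            shared = rng.standard_normal((n, 1))
            X = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal((n, p))
            n_eff = nef_adjust(X, np.full(p, 0.5)).n_effective
            assert n_eff <= previous
            previous = n_eff

    def test_pairwise_complete_handles_missing(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((500, 6))
        X[rng.random((500, 6)) < 0.1] = np.nan
        res = nef_adjust(X, np.full(6, 0.2))
        assert 1 <= res.n_effective <= 6

    def test_zero_variance_column_rejected(self):
        X = np.random.default_rng(12).standard_normal((50, 3))
        X[:, 1] = 4.2
        with pytest.raises(ValueError):
            nef_adjust(X, np.full(3, 0.5))


class TestOddsRatio:
    def test_closed_form(self):
        cell = odds_ratio_2x2(10, 20, 20, 10)
        assert cell.or_value == pytest.approx(0.25)

    def test_equal_odds_ci_straddles_one(self):
        cell = odds_ratio_2x2(5, 5, 7, 7)
        assert cell.or_value == pytest.approx(1.0)
        assert cell.ci_low < 1.0 < cell.ci_high
        assert cell.p == pytest.approx(1.0)

    def test_wald_formula_oracle(self):
        a, b, c, d = 50, 950, 100, 900
        cell = odds_ratio_2x2(a, b, c, d)
        log_or = math.log((a * d) / (b * c))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert cell.or_value == pytest.approx(math.exp(log_or), rel=1e-12)
        assert cell.or_value == pytest.approx(0.4737, abs=5e-4)
        assert cell.ci_low == pytest.approx(math.exp(log_or - 1.959964 * se), rel=1e-12)
        assert cell.ci_high == pytest.approx(math.exp(log_or + 1.959964 * se), rel=1e-12)
        assert cell.ci_low == pytest.approx(0.3333, abs=0.002)
        assert cell.ci_high == pytest.approx(0.6732, abs=0.002)
        assert cell.p == pytest.approx(2 * sps.norm.sf(abs(log_or / se)), rel=1e-12)

    def test_zero_cell_haldane_correction(self):
        cell = odds_ratio_2x2(0, 10, 5, 5)
        assert cell.corrected
        assert cell.or_value == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2(-1, 2, 3, 4)

    def test_compare_equal_odds_ratios(self):
        a = odds_ratio_2x2(20, 80, 10, 40)
        b = odds_ratio_2x2(40, 160, 20, 80)
        chi2, p = compare_odds_ratios(a, b)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_compare_different_odds_ratios(self):
        a = odds_ratio_2x2(100, 100, 50, 150)
        b = odds_ratio_2x2(30, 170, 60, 140)
        chi2, p = compare_odds_ratios(a, b)
        assert chi2 > 3.84 and p < 0.05


class TestWelch:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, _df, p = welch_t(x, x)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_swap_antisymmetry(self):
        x = np.array([1.0, 2.0, 3.0, 7.0])
        y = np.array([3.0, 4.0, 5.0, 6.0, 9.0])
        t_xy, df_xy, p_xy = welch_t(x, y)
        t_yx, df_yx, p_yx = welch_t(y, x)
        assert t_xy == pytest.approx(-t_yx)
        assert df_xy == pytest.approx(df_yx)
        assert p_xy == pytest.approx(p_yx)

    def test_textbook_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([3.0, 4.0, 5.0, 6.0])
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t_expected = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        df_expected = (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1))
        p_expected = 2 * sps.t.sf(abs(t_expected), df_expected)
        t, df, p = welch_t(x, y)
        assert t == pytest.approx(t_expected, rel=1e-12)
        assert df == pytest.approx(df_expected, rel=1e-12)
        assert p == pytest.approx(p_expected, rel=1e-12)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            welch_t([2.0, 2.0], [1.0, 3.0])
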