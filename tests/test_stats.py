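"""Nonparametric cohort statistics: median/IQR, Friedman, Dunn, Shapiro gate."""

import numpy as np
import pytest
from scipy import stats as sps

from petseg import dunn_uncorrected, friedman, median_iqr, shapiro_gate


class TestMedianIqr:
    def test_order_statistics(self):
        assert median_iqr([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)

    def test_single_value(self):
        assert median_iqr([7]) == (7.0, 7.0, 7.0)

    def test_cohort_ages(self):
        """Ten patient ages: our linear-interpolation median is 69.5.

        Clinical software that rounds half-up to integers would print 70 for
        the same data; the quantile convention here is pinned to linear
        interpolation and documented, not hidden behind rounding.
        """
        ages = [70, 66, 69, 76, 80, 53, 64, 72, 74, 66]
        med, q1, q3 = median_iqr(ages)
        assert med == 69.5
        assert q1 < med < q3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])
        with pytest.raises(ValueError):
            median_iqr([float("nan")])


PERFECTLY_ORDERED = np.array([[1.0, 2.0, 3.0]] * 3)


class TestFriedman:
    def test_perfectly_ordered_statistic(self):
        """Rank sums 3/6/9 over 3 blocks give the hand-computed statistic 6.0."""
        stat, p = friedman(PERFECTLY_ORDERED)
        assert stat == pytest.approx(6.0)
        assert 0 < p < 0.05

    def test_identical_columns(self):
        stat, p = friedman(np.ones((4, 3)))
        assert stat == 0.0 and p == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_reference(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(10, 4))
        stat, p = friedman(m)
        ref = sps.friedmanchisquare(*m.T)
        assert stat == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 4, size=(12, 4)).astype(float)
        stat, p = friedman(m)
        ref = sps.friedmanchisquare(*m.T)
        assert stat == pytest.approx(ref.statistic, abs=1e-10)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(0.5, 9.0, size=(8, 5))
        stat, _ = friedman(m)
        stat_log, _ = friedman(np.log(m))
        stat_cube, _ = friedman(m**3)
        assert stat == pytest.approx(stat_log) == pytest.approx(stat_cube)

    def test_k2_reduces_to_sign_test_statistic(self):
        """With two approaches and no ties: chi2 = (n_plus - n_minus)^2 / n."""
        rng = np.random.default_rng(3)
        a = rng.normal(size=15)
        b = a + rng.normal(size=15) * 0.5 + 0.3
        m = np.column_stack([a, b])
        n_plus = int((b > a).sum())
        n_minus = int((a > b).sum())
        stat, _ = friedman(m)
        assert stat == pytest.approx((n_plus - n_minus) ** 2 / 15.0)

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, 2.0], [np.nan, 1.0]])
        with pytest.raises(ValueError, match="complete"):
            friedman(m)


class TestDunn:
    def test_extreme_pair_closed_form(self):
        """Mean ranks 1 vs 3 at n=3, k=3: z = 2/sqrt(12/18) = 2.449, p = 0.0143."""
        report = dunn_uncorrected(PERFECTLY_ORDERED)
        pair = [p for p in report.pairwise if (p.approach_i, p.approach_j) == (0, 2)][0]
        assert abs(pair.z) == pytest.approx(2.449, abs=1e-3)
        assert pair.p == pytest.approx(0.0143, abs=1e-3)
        assert pair.significant

    def test_identical_columns_all_null(self):
        report = dunn_uncorrected(np.ones((5, 4)))
        for pair in report.pairwise:
            assert pair.z == 0.0
            assert pair.p == 1.0
            assert not pair.significant

    def test_significance_flag_is_strict_inequality(self):
        report = dunn_uncorrected(PERFECTLY_ORDERED, alpha=0.0143)
        pair = [p for p in report.pairwise if (p.approach_i, p.approach_j) == (0, 2)][0]
        # p = 0.01430588... > alpha boundary 0.0143 -> strict < means not flagged
        assert pair.significant == (pair.p < 0.0143)

    def test_antisymmetry_via_column_swap(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=(8, 3))
        z_orig = {(p.approach_i, p.approach_j): p.z for p in dunn_uncorrected(m).pairwise}
        swapped = m[:, [1, 0, 2]]
        z_swap = {(p.approach_i, p.approach_j): p.z for p in dunn_uncorrected(swapped).pairwise}
        assert z_swap[(0, 1)] == pytest.approx(-z_orig[(0, 1)])

    def test_rank_sums_per_block(self):
        """Tie-free within-block ranks always sum to k(k+1)/2."""
        rng = np.random.default_rng(5)
        m = rng.normal(size=(6, 4))
        from scipy.stats import rankdata

        for row in m:
            assert rankdata(row).sum() == 10.0


class TestShapiroGate:
    def test_heavy_tailed_mixture_flagged(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 1, 17), rng.normal(0, 12, 3)])
        p, non_normal = shapiro_gate(x)
        assert non_normal and p < 0.05

    def test_constant_vector_not_available(self):
        p, non_normal = shapiro_gate([4.0, 4.0, 4.0, 4.0])
        assert p is None and not non_normal

    def test_too_few_values_not_available(self):
        p, non_normal = shapiro_gate([1.0, 2.0])
        assert p is None and not non_normal

    def test_gaussian_type_one_rate(self):
        """Standard-normal samples pass the screen in at least 90% of seeds."""
        flags = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            _, non_normal = shapiro_gate(rng.normal(size=500))
            flags.append(non_normal)
        assert np.mean(flags) <= 0.10
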