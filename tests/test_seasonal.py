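"""Descriptive summaries, the Friedman rank test (with its exact sign-test
oracle at k = 2), and the Kolmogorov-Smirnov normality check."""

import itertools

import numpy as np
import pytest
from scipy import stats

from btexrisk import (
    CohortSpec,
    descriptive_summary,
    friedman_test,
    generate_cohort,
    ks_normality,
    seasonal_comparison_table,
)


class TestDescriptive:
    def test_textbook_case(self):
        s = descriptive_summary([1, 2, 3])
        assert s.range == (1, 3) and s.mean == 2 and s.sd == 1

    def test_constant_vector_has_zero_sd(self):
        assert descriptive_summary([4.0, 4.0, 4.0]).sd == 0.0

    def test_single_value_has_absent_sd(self):
        assert descriptive_summary([3.0]).sd is None

    def test_mean_within_range(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0, 1, 50)
        s = descriptive_summary(x)
        assert s.minimum <= s.mean <= s.maximum


def exact_sign_test_p(n: int, b_obs: int) -> float:
    """Exact permutation p for the k=2 Friedman statistic: enumerate all
    2^n equally likely within-block orderings and accumulate the mass of
    sign patterns at least as extreme as the observed count."""
    d_obs = abs(2 * b_obs - n)
    hits = sum(
        1 for signs in itertools.product((0, 1), repeat=n) if abs(2 * sum(signs) - n) >= d_obs
    )
    return hits / 2**n


class TestFriedman:
    def test_unanimous_seasonal_increase(self):
        m = np.column_stack([np.arange(10), np.arange(10) + 1.0])
        res = friedman_test(m)
        assert res.statistic == pytest.approx(10.0)
        assert res.rank_sums == (10.0, 20.0)
        assert res.pvalue == pytest.approx(stats.chi2.sf(10.0, 1), rel=1e-12)

    def test_identical_columns_give_null_result(self):
        m = np.column_stack([np.arange(5.0), np.arange(5.0)])
        res = friedman_test(m)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_fully_tied_block_contributes_nothing(self):
        informative = np.array([[1.0, 2.0], [1.0, 3.0], [2.0, 4.0]])
        with_tied = np.vstack([informative, [5.0, 5.0]])
        a, b = friedman_test(informative), friedman_test(with_tied)
        # the tied block enters n but adds no rank signal
        assert b.statistic <= a.statistic

    def test_statistic_matches_sign_test_identity_for_k2(self):
        """Without ties at k=2 the statistic is exactly (2b-n)^2/n with b
        the number of blocks where column 2 exceeds column 1."""
        rng = np.random.default_rng(12)
        for n in range(2, 13):
            for b in range(n + 1):
                base = rng.uniform(1, 2, n)
                delta = np.where(np.arange(n) < b, 0.5, -0.5)
                m = np.column_stack([base, base + delta])
                res = friedman_test(m)
                assert res.statistic == pytest.approx((2 * b - n) ** 2 / n, rel=1e-12)

    def test_pvalue_tracks_exact_enumeration_oracle(self):
        """The chi-square tail is a continuous approximation to the discrete
        sign-test null; over all n <= 12 its absolute error never exceeds
        0.44 (0.27 for n >= 8), shrinking as n grows."""
        for n in range(2, 13):
            envelope = 0.44 if n < 8 else 0.27
            for b in range(n + 1):
                p_chi = float(stats.chi2.sf((2 * b - n) ** 2 / n, 1))
                p_exact = exact_sign_test_p(n, b)
                assert abs(p_chi - p_exact) <= envelope

    def test_invariant_to_monotone_transform_of_blocks(self):
        rng = np.random.default_rng(5)
        m = rng.lognormal(0, 1, (12, 3))
        res = friedman_test(m)
        res_log = friedman_test(np.log(m))
        res_affine = friedman_test(3.0 * m + 7.0)
        assert res_log.statistic == pytest.approx(res.statistic)
        assert res_affine.statistic == pytest.approx(res.statistic)

    def test_agrees_with_scipy_at_k3(self):
        rng = np.random.default_rng(8)
        m = rng.normal(0, 1, (15, 3))
        res = friedman_test(m)
        ref_stat, ref_p = stats.friedmanchisquare(*(m[:, j] for j in range(3)))
        assert res.statistic == pytest.approx(ref_stat)
        assert res.pvalue == pytest.approx(ref_p)

    def test_incomplete_matrix_rejected(self):
        with pytest.raises(ValueError):
            friedman_test(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestKSNormality:
    def test_statistic_bounded(self):
        rng = np.random.default_rng(0)
        res = ks_normality(rng.normal(0, 1, 100))
        assert 0.0 <= res.statistic <= 1.0
        assert res.params_estimated

    def test_null_retention_rate(self):
        """Gaussian samples at n=1e4: the (conservative) p stays above 0.05
        in at least 95 of 100 seeded replicates."""
        keep = sum(
            ks_normality(np.random.default_rng(seed).normal(0, 1, 10_000)).pvalue > 0.05
            for seed in range(100)
        )
        assert keep >= 95

    def test_power_against_exponential(self):
        """Exponential samples at n=500 are rejected in >= 99 of 100
        replicates despite the conservative p-value."""
        reject = sum(
            ks_normality(np.random.default_rng(seed).exponential(1.0, 500)).pvalue < 0.05
            for seed in range(100)
        )
        assert reject >= 99

    def test_statistic_matches_reference_implementation(self):
        """Cross-check D against the Lilliefors statistic from statsmodels."""
        from statsmodels.stats.diagnostic import lilliefors

        rng = np.random.default_rng(2)
        x = rng.gamma(2.0, 1.0, 200)
        d_ref, _ = lilliefors(x, dist="norm", pvalmethod="approx")
        assert ks_normality(x).statistic == pytest.approx(d_ref, rel=1e-9)

    def test_constant_sample_degenerate(self):
        with pytest.raises(ValueError):
            ks_normality([2.0] * 10)


class TestSeasonalComparisonTable:
    def test_paired_table_structure_and_counts(self):
        cohort = generate_cohort(CohortSpec(n_subjects=24, seed=3))
        table = seasonal_comparison_table(cohort)
        assert len(table) == 16  # 4 workstations x 4 analytes
        assert (table["n_subjects"] == 6).all()  # equal allocation of 24
        assert {"summer_mean", "winter_mean", "chi2_f", "pvalue", "significant"} <= set(
            table.columns
        )
        assert table["pvalue"].between(0, 1).all()
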