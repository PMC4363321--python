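import itertools

import numpy as np
import pytest
from scipy import stats as sps

from relca.stats import (
    DegenerateStatisticsError,
    friedman,
    median_ci,
    normality_check,
    paired_t,
    percentile_summary,
    posthoc_cluster,
    wilcoxon_signed_rank,
)


def signed_rank_p_by_enumeration(d, alternative="two-sided"):
    """Brute-force exact p: the null distribution of W+ over all 2^n sign
    assignments of the observed |d| midranks."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0.0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = np.array(
        [np.dot(signs, ranks) for signs in itertools.product([0, 1], repeat=n)]
    )
    tol = 1e-9
    p_le = np.mean(ws <= w_obs + tol)
    p_ge = np.mean(ws >= w_obs - tol)
    if alternative == "greater":
        return min(1.0, p_ge)
    if alternative == "less":
        return min(1.0, p_le)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_all_positive_small_sample(self):
        rep = wilcoxon_signed_rank([1, 2, 3, 4, 5], ci_level=0.9)
        assert rep.p_value == pytest.approx(0.0625)
        assert rep.statistic == 15.0
        assert rep.extra["method"] == "exact"

    def test_symmetric_pairs_give_p_one(self):
        rep = wilcoxon_signed_rank([-1, 1, -2, 2, -3, 3], ci_level=0.9)
        assert rep.p_value == 1.0
        assert rep.median_difference == 0.0

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateStatisticsError):
            wilcoxon_signed_rank([0.0] * 20)

    def test_too_few_nonzero(self):
        with pytest.raises(ValueError, match="n >= 5"):
            wilcoxon_signed_rank([1.0, -2.0, 3.0, 0.0, 0.0, 0.0, 0.0, 0.0])

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_path_matches_sign_enumeration(self, alternative):
        r = np.random.default_rng(123)
        for _ in range(30):
            n = int(r.integers(6, 13))
            d = np.round(r.normal(0.3, 1.0, n), 1)
            d[d == 0.0] = 0.1
            rep = wilcoxon_signed_rank(d, alternative=alternative, ci_level=0.9)
            expected = signed_rank_p_by_enumeration(d, alternative)
            assert rep.p_value == pytest.approx(expected, rel=1e-12)

    def test_approximation_agrees_with_scipy(self):
        r = np.random.default_rng(5)
        for _ in range(10):
            d = r.normal(0.2, 1.0, 80)
            rep = wilcoxon_signed_rank(d)
            ref = sps.wilcoxon(d, correction=True, method="approx")
            assert rep.extra["method"] == "normal-approximation"
            assert rep.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_nonzero_null_value(self):
        # shifting the data by mu0 must reproduce the mu0 = 0 test
        d = np.array([0.5, 1.2, -0.3, 2.0, 1.1, 0.7, -0.2, 0.9])
        rep0 = wilcoxon_signed_rank(d)
        rep1 = wilcoxon_signed_rank(d + 10.0, mu0=10.0)
        assert rep1.p_value == pytest.approx(rep0.p_value)


class TestPairedT:
    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateStatisticsError):
            paired_t([1.0, 1.0, 1.0, 1.0])

    def test_symmetric_three_points(self):
        rep = paired_t([-1.0, 0.0, 1.0])
        assert rep.statistic == pytest.approx(0.0)
        assert rep.p_value == pytest.approx(1.0)

    def test_type_one_error_calibration(self):
        """Null rejection rate at alpha = 0.05 stays in [0.04, 0.06] over
        10^4 replications at n = 30."""
        r = np.random.default_rng(99)
        d = r.normal(0.0, 1.0, (10_000, 30))
        res = sps.ttest_1samp(d, 0.0, axis=1)
        # sanity: vectorized scipy equals our per-vector wrapper
        rep = paired_t(d[0])
        assert rep.p_value == pytest.approx(res.pvalue[0])
        rate = float(np.mean(res.pvalue < 0.05))
        assert 0.04 < rate < 0.06


class TestFriedman:
    def test_identical_columns_give_zero_statistic(self):
        m = np.tile(np.arange(12.0)[:, None], (1, 3))
        stat, p = friedman(m)
        assert stat == 0.0 and p == 1.0

    def test_hand_ranked_oracle(self):
        m = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 1.0], [1.0, 3.0, 2.0]] * 4)
        stat, _ = friedman(m)
        # classical no-tie formula on hand-computed within-row ranks
        ranks = np.array([[1, 2, 3], [2, 3, 1], [1, 3, 2]] * 4)
        n, k = m.shape
        expected = 12.0 / (n * k * (k + 1)) * (ranks.sum(0) ** 2).sum() - 3 * n * (k + 1)
        assert stat == pytest.approx(expected)

    def test_matches_scipy_on_random_data(self):
        r = np.random.default_rng(3)
        m = r.normal(0, 1, (40, 4)) + np.array([0.0, 0.2, 0.4, 0.1])
        stat, p = friedman(m)
        ref = sps.friedmanchisquare(*m.T)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_two_columns_redirects_to_wilcoxon(self):
        with pytest.raises(ValueError, match="wilcoxon"):
            friedman(np.ones((20, 2)))


class TestPosthocCluster:
    def _shifted(self, shifts, n=60, scale=1.0, seed=0):
        r = np.random.default_rng(seed)
        base = r.normal(0.0, scale, (n, 1))
        noise = r.normal(0.0, scale, (n, len(shifts)))
        return base + noise + np.asarray(shifts)

    def test_strong_separation_gives_singletons(self):
        m = self._shifted([0.0, 10.0, 20.0])
        res = posthoc_cluster(m, ["a", "b", "c"])
        assert res.ranks == {"a": 1, "b": 2, "c": 3}
        assert res.labels == {"a": "green", "b": "yellow", "c": "red"}

    def test_identical_alternatives_form_one_cluster(self):
        r = np.random.default_rng(1)
        base = r.normal(0.0, 1.0, (50, 1))
        m = base + r.normal(0.0, 0.05, (50, 3))
        res = posthoc_cluster(m, ["a", "b", "c"])
        assert set(res.ranks.values()) == {1}

    def test_two_group_structure(self):
        m = self._shifted([0.0, 0.02, 15.0])
        res = posthoc_cluster(m, ["a", "b", "c"])
        assert res.ranks["a"] == res.ranks["b"] == 1
        assert res.ranks["c"] == 2

    @pytest.mark.parametrize("method", ["nonparametric", "parametric"])
    def test_input_order_invariance(self, method):
        m = self._shifted([0.0, 0.3, 8.0], seed=7)
        res1 = posthoc_cluster(m, ["a", "b", "c"], method=method)
        res2 = posthoc_cluster(m[:, ::-1], ["c", "b", "a"], method=method)
        assert res1.ranks == res2.ranks

    def test_parametric_path_strong_separation(self):
        m = self._shifted([0.0, 10.0, 20.0], seed=2)
        res = posthoc_cluster(m, ["a", "b", "c"], method="parametric")
        assert res.omnibus_test == "two-way-anova"
        assert res.ranks == {"a": 1, "b": 2, "c": 3}

    def test_holm_never_rejects_more_than_uncorrected(self):
        r = np.random.default_rng(11)
        m = r.normal(0, 1, (40, 4)) + np.array([0.0, 0.3, 0.5, 0.8])
        res = posthoc_cluster(m, list("abcd"))
        raw_rejects = 0
        for i, j in itertools.combinations(range(4), 2):
            raw_rejects += wilcoxon_signed_rank(m[:, i] - m[:, j]).reject
        corrected_rejects = sum(
            p < 0.05 for p in res.pairwise_p.values()
        )
        assert corrected_rejects <= raw_rejects


class TestMedianCI:
    def test_order_statistic_ranks_at_n_1000(self):
        # data equal to 1..n: the interval is exactly the order statistics
        x = np.arange(1.0, 1001.0)
        med, lo, hi = median_ci(x)
        assert med == 500.5
        assert (lo, hi) == (469.0, 532.0)

    def test_constant_data(self):
        assert median_ci([3.0] * 20) == (3.0, 3.0, 3.0)

    def test_small_n_refused(self):
        with pytest.raises(ValueError, match="n >= 6"):
            median_ci([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="too small"):
            median_ci(np.arange(8.0), level=0.999)

    def test_coverage_at_least_nominal(self):
        """Conservative order-statistic CI covers the true median in at
        least 95% of 2000 normal samples at n = 100."""
        r = np.random.default_rng(17)
        hits = 0
        for _ in range(2000):
            x = r.normal(0.0, 1.0, 100)
            _, lo, hi = median_ci(x)
            hits += lo <= 0.0 <= hi
        assert hits / 2000 >= 0.95


class TestSummaries:
    def test_percentiles_linear_interpolation(self):
        q = percentile_summary(np.arange(1.0, 101.0))
        assert q["p10"] == pytest.approx(10.9)
        assert q["median"] == pytest.approx(50.5)
        assert q["p90"] == pytest.approx(90.1)

    def test_constant_vector(self):
        q = percentile_summary([2.0] * 15)
        assert set(q.values()) == {2.0}

    def test_monotone_ordering(self):
        q = percentile_summary(np.random.default_rng(0).lognormal(0, 1, 500))
        assert q["p10"] <= q["p25"] <= q["median"] <= q["p75"] <= q["p90"]

    def test_small_n_refused(self):
        with pytest.raises(ValueError):
            percentile_summary(np.arange(5.0))


class TestNormalityCheck:
    def test_normal_data_passes_gate(self):
        hits = 0
        for seed in range(20):
            d = np.random.default_rng(seed).normal(0, 1, 1000)
            _, _, is_normal = normality_check(d)
            hits += is_normal
        assert hits >= 18

    def test_lognormal_data_fails_gate(self):
        d = np.random.default_rng(0).lognormal(0, 1, 1000)
        _, p, is_normal = normality_check(d)
        assert not is_normal and p < 1e-6

    def test_small_n_refused(self):
        with pytest.raises(ValueError, match="nonparametric"):
            normality_check([1.0] * 5)
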