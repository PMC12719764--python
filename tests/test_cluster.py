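"""Point-wise statistics and cluster-based permutation correction."""

import numpy as np
import pytest
from scipy import stats as sstats

import dyadcoh as dc
from dyadcoh.cluster import _clusters_from_stat, _max_mass


class TestPointwisePairedT:
    def test_equal_inputs_give_zero(self, rng):
        a = rng.standard_normal((10, 8))
        t = dc.pointwise_paired_t(a, a.copy())
        assert np.allclose(t, 0.0)

    def test_constant_positive_difference_gives_large_positive_t(self, rng):
        a = rng.standard_normal((12, 6))
        b = a - 1.0 + 0.001 * rng.standard_normal((12, 6))
        t = dc.pointwise_paired_t(a, b)
        assert np.all(t > 100)

    def test_matches_scipy_oracle(self, rng):
        a = rng.standard_normal((10, 5))
        b = rng.standard_normal((10, 5))
        t = dc.pointwise_paired_t(a, b)
        for f in range(5):
            ref = sstats.ttest_rel(a[:, f], b[:, f]).statistic
            assert t[f] == pytest.approx(ref, abs=1e-10)

    def test_zero_variance_flagged_infinite(self):
        a = np.ones((5, 2))
        b = np.zeros((5, 2))
        t = dc.pointwise_paired_t(a, b)
        assert np.all(np.isinf(t)) and np.all(t > 0)

    def test_nan_pairs_dropped(self, rng):
        a = rng.standard_normal((10, 3))
        b = rng.standard_normal((10, 3))
        a2 = a.copy()
        a2[0, 1] = np.nan
        t = dc.pointwise_paired_t(a2, b)
        ref = sstats.ttest_rel(a[1:, 1], b[1:, 1]).statistic
        assert t[1] == pytest.approx(ref, abs=1e-10)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            dc.pointwise_paired_t(rng.standard_normal((2, 4)),
                                  rng.standard_normal((2, 4)))


class TestPointwiseCorrelation:
    def test_perfect_linear_relation(self, rng):
        x = rng.standard_normal((8, 4))
        r, t = dc.pointwise_correlation(x, 2 * x + 1, return_r=True)
        assert np.allclose(r, 1.0)

    def test_matches_hand_computed_six_points(self):
        # six printed pairs, r computed by hand via the product-moment formula
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        # sums: Sx=21, Sy=21, Sxy=88, Sxx=91, Syy=91
        # r = (6*88-21*21)/sqrt((6*91-441)(6*91-441)) = 87/105
        r, t = dc.pointwise_correlation(x[:, None], y[:, None], return_r=True)
        assert r[0] == pytest.approx(87.0 / 105.0, abs=1e-12)
        ref = sstats.pearsonr(x, y).statistic
        assert r[0] == pytest.approx(ref, abs=1e-12)

    def test_null_false_positive_rate(self, rng):
        """|r| exceeds the two-sided 0.05 critical value in ~5% of
        frequencies for independent Gaussians (n=56)."""
        n, reps = 56, 400
        tcrit = sstats.t.ppf(0.975, df=n - 2)
        x = rng.standard_normal((n, reps))
        y = rng.standard_normal((n, reps))
        t = dc.pointwise_correlation(x, y)
        rate = np.mean(np.abs(t) > tcrit)
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 2.5 * se

    def test_constant_column_undefined(self, rng):
        x = rng.standard_normal((6, 2))
        y = x + 0.1 * rng.standard_normal((6, 2))
        y[:, 0] = 3.14
        t = dc.pointwise_correlation(x, y)
        assert np.isnan(t[0]) and np.isfinite(t[1])


class TestClusterFormation:
    def test_subthreshold_series_gives_no_clusters(self, rng):
        d = 0.01 * rng.standard_normal((10, 20))
        t = dc.pointwise_paired_t(d, np.zeros_like(d))
        res = dc.cluster_permutation(t, d, n_perm=50, seed=0)
        if res.clusters:  # tiny t-values may sporadically cross; none large
            assert all(c.p_value > 0.05 for c in res.clusters)
        assert _clusters_from_stat(np.zeros(10), 2.0) == []

    def test_clusters_are_maximal_contiguous_runs(self):
        stat = np.array([0.0, 3.0, 4.0, 0.0, 5.0, 0.0])
        cl = _clusters_from_stat(stat, 2.0)
        assert [(c[0], c[1]) for c in cl] == [(1, 2), (4, 4)]
        assert cl[0][2] == pytest.approx(7.0)
        assert _max_mass(stat, 2.0) == pytest.approx(7.0)

    def test_nan_treated_subthreshold(self):
        stat = np.array([3.0, np.nan, 3.0])
        cl = _clusters_from_stat(stat, 2.0)
        assert len(cl) == 2


class TestClusterPermutation:
    def test_exhaustive_enumeration_matches_independent_oracle(self, rng):
        """n=5 subjects: the exact null equals a separately coded
        enumeration of all 32 sign patterns, and Monte-Carlo agrees."""
        n, F = 5, 12
        d = rng.standard_normal((n, F)) + 0.8
        t = dc.pointwise_paired_t(d, np.zeros_like(d))
        res = dc.cluster_permutation(t, d, exact=True, seed=0)
        assert res.n_permutations == 32

        # independent oracle
        thr = sstats.t.ppf(0.975, df=n - 1)
        oracle = []
        for bits in range(32):
            s = np.array([1.0 if (bits >> k) & 1 else -1.0 for k in range(n)])
            ds = d * s[:, None]
            ts = ds.mean(0) / (ds.std(0, ddof=1) / np.sqrt(n))
            supra = np.abs(ts) > thr
            best, run = 0.0, 0.0
            for i in range(F):
                run = run + abs(ts[i]) if supra[i] else 0.0
                best = max(best, run)
            oracle.append(best)
        assert np.allclose(np.sort(res.null_max_mass), np.sort(oracle))

        mc = dc.cluster_permutation(t, d, n_perm=2000, seed=1)
        for ce, cm in zip(res.clusters, mc.clusters):
            assert cm.p_value == pytest.approx(ce.p_value, abs=0.05)

    def test_two_sided_symmetry(self, rng):
        d = rng.standard_normal((10, 30)) + 0.5
        t1 = dc.pointwise_paired_t(d, np.zeros_like(d))
        t2 = dc.pointwise_paired_t(np.zeros_like(d), d)
        assert np.allclose(t1, -t2)
        r1 = dc.cluster_permutation(t1, d, n_perm=500, seed=3)
        r2 = dc.cluster_permutation(t2, -d, n_perm=500, seed=3)
        assert [c.mass for c in r1.clusters] == pytest.approx(
            [c.mass for c in r2.clusters])
        assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]

    def test_add_one_pvalues_never_zero(self, rng):
        d = rng.standard_normal((8, 10)) + 3.0
        t = dc.pointwise_paired_t(d, np.zeros_like(d))
        res = dc.cluster_permutation(t, d, n_perm=100, seed=0)
        assert res.clusters
        for c in res.clusters:
            assert c.p_value >= 1.0 / 101.0
        raw = dc.cluster_permutation(t, d, n_perm=100, seed=0,
                                     p_convention="raw")
        assert min(c.p_value for c in raw.clusters) == 0.0

    def test_deterministic_given_seed(self, rng):
        d = rng.standard_normal((9, 15)) + 0.6
        t = dc.pointwise_paired_t(d, np.zeros_like(d))
        r1 = dc.cluster_permutation(t, d, n_perm=200, seed=42)
        r2 = dc.cluster_permutation(t, d, n_perm=200, seed=42)
        assert np.array_equal(r1.null_max_mass, r2.null_max_mass)

    def test_correlation_variant_shuffles_subjects(self, rng):
        n, F = 20, 10
        x = rng.standard_normal((n, F))
        y = x + 0.3 * rng.standard_normal((n, F))
        t = dc.pointwise_correlation(x, y)
        res = dc.cluster_permutation(t, (x, y), n_perm=300, seed=0,
                                     kind="correlation")
        assert res.clusters and res.clusters[0].p_value < 0.05

    def test_freqs_annotated(self, rng):
        d = rng.standard_normal((8, 6)) + 2.0
        t = dc.pointwise_paired_t(d, np.zeros_like(d))
        freqs = np.arange(6) * 0.2
        res = dc.cluster_permutation(t, d, n_perm=50, seed=0, freqs=freqs)
        for c in res.clusters:
            assert c.freq_lo == freqs[c.start] and c.freq_hi == freqs[c.stop]
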