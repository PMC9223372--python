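"""Shuffle null, permutation enrichment, BH, binomial and rank-sum tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import brute_binom_two_sided, brute_ranksum_exact, random_interval_set
from rloopkit import (
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    bh_adjust,
    chromosome_density_test,
    permutation_enrichment,
    rank_sum_test,
    shuffle_intervals,
)
from rloopkit.simulate import generate_null_peaks


class TestShuffleIntervals:
    def test_conserves_chromosomes_and_width_multiset(self, toy_genome, rng):
        peaks = random_interval_set(rng, toy_genome, 200)
        for seed in range(5):
            shuffled = shuffle_intervals(peaks, toy_genome, seed)
            assert sorted(shuffled.chroms) == sorted(peaks.chroms)
            for chrom, idx in peaks.by_chrom().items():
                sidx = shuffled.by_chrom()[chrom]
                assert sorted(shuffled.widths[sidx]) == sorted(peaks.widths[idx])

    def test_full_width_interval_is_forced_to_zero(self):
        g = GenomeLayout((("c", 500),))
        peaks = IntervalSet(["c"], [0], [500], genome=g)
        out = shuffle_intervals(peaks, g, seed=123)
        assert out.starts.tolist() == [0]

    def test_wider_than_chromosome_errors(self):
        g = GenomeLayout((("c", 500), ("d", 100)))
        peaks = IntervalSet(["d"], [0], [100], genome=g)
        peaks.ends = peaks.ends + 50  # corrupt beyond length
        with pytest.raises(ValueError, match="wider"):
            shuffle_intervals(peaks, GenomeLayout((("c", 500), ("d", 120))), 0)

    def test_start_positions_uniform(self):
        """10,000 shuffles of one 100 bp peak on a 10 kb arm pass chi-square
        uniformity over 10 equal start-position bins at alpha = 0.01."""
        g = GenomeLayout((("c", 10000),))
        peaks = IntervalSet(["c"], [0], [100], genome=g)
        rng = np.random.default_rng(7)
        starts = [
            int(shuffle_intervals(peaks, g, rng).starts[0]) for _ in range(10000)
        ]
        # valid starts are 0..9900; bin into 10 equal cells
        counts, _ = np.histogram(starts, bins=10, range=(0, 9901))
        p = stats.chisquare(counts).pvalue
        assert p > 0.01


class TestPermutationEnrichment:
    def test_saturating_feature(self, toy_genome, rng):
        peaks = random_interval_set(rng, toy_genome, 50)
        everything = IntervalSet.from_intervals(
            [GenomicInterval(c, 0, l) for c, l in toy_genome.entries],
            genome=toy_genome,
        )
        (res,) = permutation_enrichment(
            peaks, {"all": everything}, toy_genome, n_perm=100, seed=0
        )
        assert res.observed == 50
        assert res.expected_mean == 50.0
        assert res.log2_ratio == 0.0
        assert res.p_perm == 1.0

    def test_resolution_floor(self, toy_genome, rng):
        peaks = random_interval_set(rng, toy_genome, 20)
        feat = random_interval_set(rng, toy_genome, 5)
        (res,) = permutation_enrichment(
            peaks, {"f": feat}, toy_genome, n_perm=10, seed=1
        )
        assert res.p_perm >= 1 / 11

    def test_empty_feature_label(self, toy_genome, rng):
        peaks = random_interval_set(rng, toy_genome, 10)
        empty = IntervalSet([], [], [], genome=toy_genome)
        (res,) = permutation_enrichment(
            peaks, {"none": empty}, toy_genome, n_perm=50, seed=2
        )
        assert res.observed == 0
        assert res.expected_mean == 0.0
        assert np.isnan(res.log2_ratio)
        assert res.p_perm == 1.0

    def test_empty_peaks_error(self, toy_genome):
        empty = IntervalSet([], [], [], genome=toy_genome)
        with pytest.raises(ValueError, match="empty peak set"):
            permutation_enrichment(empty, {"f": empty}, toy_genome, n_perm=10, seed=0)

    def test_matches_exhaustive_enumeration_oracle(self):
        """On a 20 bp single-arm genome the shuffle null is fully enumerable;
        the empirical two-sided p must agree with the exact placement
        enumeration within Monte Carlo error (4 SD at n_perm = 5000)."""
        g = GenomeLayout((("c", 20),))
        peaks = IntervalSet(["c", "c"], [0, 5], [3, 10], genome=g)  # widths 3, 5
        feature = IntervalSet(["c"], [8], [12], genome=g)
        widths = [3, 5]
        fs, fe = 8, 12

        def overlap(s, w):
            return int(s < fe and fs < s + w)

        counts = []
        for s1 in range(20 - widths[0] + 1):
            for s2 in range(20 - widths[1] + 1):
                counts.append(overlap(s1, widths[0]) + overlap(s2, widths[1]))
        counts = np.asarray(counts)
        observed = overlap(0, 3) + overlap(5, 5)
        ge = np.mean(counts >= observed)
        le = np.mean(counts <= observed)
        p_exact = min(1.0, 2 * min(ge, le))
        (res,) = permutation_enrichment(
            peaks, {"f": feature}, g, n_perm=5000, seed=3
        )
        mc_sd = np.sqrt(p_exact * (1 - p_exact) / 5000)
        assert res.p_perm == pytest.approx(p_exact, abs=max(4 * mc_sd, 0.01))
        assert res.expected_mean == pytest.approx(counts.mean(), abs=0.05)

    def test_null_calibration_is_not_anticonservative(self, rng):
        """Type-I error of the permutation p on null peak sets stays near or
        below nominal (small-scale check; the full calibration runs at
        acceptance scale)."""
        from rloopkit.simulate import SyntheticConfig, generate

        ds = generate(SyntheticConfig(seed=11, n_peaks=10))
        features = ds.state_features()
        rejections = 0
        n_rep = 40
        for i in range(n_rep):
            null = generate_null_peaks(ds.genome, 500, seed=1000 + i)
            results = permutation_enrichment(
                null, features, ds.genome, n_perm=200, seed=2000 + i
            )
            rejections += any(r.p_perm < 0.05 for r in results)
        # 5 features, each at most ~5% -> family-wise well under 25%
        assert rejections / n_rep < 0.3


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_all_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_hand_computed_step_up(self):
        got = bh_adjust([0.01, 0.04, 0.03, 0.005])
        assert got == pytest.approx([0.02, 0.04, 0.04, 0.02])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([1.5])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=1e-9, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=20,
        ),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance_and_bound(self, pvals, rnd):
        q = bh_adjust(pvals)
        assert all(0 < x <= 1 for x in q)
        order = list(range(len(pvals)))
        rnd.shuffle(order)
        q_perm = bh_adjust([pvals[i] for i in order])
        assert np.allclose([q_perm[order.index(i)] for i in range(len(q))], q)


class TestChromosomeDensityTest:
    def _genome(self):
        return GenomeLayout(
            (("A1", 3_000_000), ("A2", 3_000_000), ("X", 2_000_000)),
        )

    def test_null_configuration_not_significant(self, rng):
        g = self._genome()  # X = 25% of genome
        n_x, n_a = 25, 75
        peaks = IntervalSet(
            ["X"] * n_x + ["A1"] * n_a,
            list(rng.integers(0, 1_000_000, n_x + n_a)),
            list(rng.integers(0, 1_000_000, n_x + n_a) + 1_000_001),
            genome=None,
        )
        res = chromosome_density_test(peaks, g)
        assert res.p0 == pytest.approx(0.25)
        assert res.p_binom > 0.9

    def test_matches_enumeration_oracle(self):
        g = self._genome()
        peaks = IntervalSet(["X"] * 9 + ["A1"], [0] * 10, [100] * 10)
        res = chromosome_density_test(peaks, g)
        assert res.x_count == 9
        assert res.p_binom == pytest.approx(brute_binom_two_sided(9, 10, 0.25), rel=1e-9)

    def test_extreme_all_on_x(self):
        g = GenomeLayout((("A1", 8_000_000), ("X", 2_000_000)))
        peaks = IntervalSet(["X"] * 20, [0] * 20, [100] * 20)
        res = chromosome_density_test(peaks, g)
        assert res.p_binom == pytest.approx(brute_binom_two_sided(20, 20, 0.2), rel=1e-6)
        assert res.p_binom < 1e-10

    def test_per_chrom_density_units(self):
        g = self._genome()
        peaks = IntervalSet(["A1"] * 6, [0] * 6, [10] * 6)
        res = chromosome_density_test(peaks, g)
        assert res.per_chrom_density["A1"] == pytest.approx(2.0)  # 6 per 3 Mb

    def test_random_counts_match_oracle(self, rng):
        g = self._genome()
        for _ in range(30):
            n = int(rng.integers(1, 60))
            k = int(rng.integers(0, n + 1))
            peaks = IntervalSet(
                ["X"] * k + ["A2"] * (n - k), [0] * n, [50] * n
            )
            res = chromosome_density_test(peaks, g)
            assert res.p_binom == pytest.approx(
                brute_binom_two_sided(k, n, 0.25), rel=1e-8
            )

    def test_no_x_flag_errors(self):
        g = GenomeLayout((("A1", 100),), x_chroms=frozenset())
        peaks = IntervalSet(["A1"], [0], [10])
        with pytest.raises(ValueError, match="X-flagged"):
            chromosome_density_test(peaks, g)

    def test_null_rejection_rate_calibrated(self, rng):
        """With length-proportional placement the binomial test rejects at
        alpha = 0.05 in roughly a nominal fraction of replicates."""
        g = self._genome()
        rejections = 0
        for i in range(200):
            k = rng.binomial(300, 0.25)
            peaks = IntervalSet(
                ["X"] * k + ["A1"] * (300 - k), [0] * 300, [50] * 300
            )
            rejections += chromosome_density_test(peaks, g).p_binom < 0.05
        assert rejections / 200 <= 0.08


class TestRankSum:
    def test_identical_multisets_give_p_one(self):
        _, p = rank_sum_test([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert p == 1.0

    def test_all_constant_gives_p_one(self):
        _, p = rank_sum_test([5.0, 5.0], [5.0, 5.0, 5.0])
        assert p == 1.0

    def test_exact_small_sample(self):
        _, p = rank_sum_test([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 6))
            m = int(rng.integers(2, 6))
            vals = rng.permutation(100)[: n + m].astype(float)
            a, b = vals[:n], vals[n:]
            u, p = rank_sum_test(a, b)
            u_o, p_o = brute_ranksum_exact(a, b)
            assert u == pytest.approx(u_o)
            assert p == pytest.approx(p_o)

    def test_asymptotic_close_to_exact(self, rng):
        """Normal approximation with continuity correction agrees with the
        exact enumeration within 0.02 at n = 6 + 6."""
        for _ in range(20):
            vals = rng.permutation(1000)[:13].astype(float)
            a, b = vals[:6], vals[6:]  # 6 + 7 forces the asymptotic branch
            _, p_approx = rank_sum_test(a, b)
            _, p_exact = brute_ranksum_exact(a, b)
            assert abs(p_approx - p_exact) < 0.02
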