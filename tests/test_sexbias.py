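"""DE-group summaries, motif scanning, gene labelling, group comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_scan_motif
from rloopkit import (
    DEGroupTable,
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    MotifModel,
    de_chromosome_profile,
    debias_summary,
    group_compare,
    label_genes,
    motif_density_ratio,
    presence_filter,
    scan_motif,
    summarize_de_counts,
)


class TestDebiasSummary:
    def test_published_style_counts(self):
        """13441 shared + 558 female- + 1282 male-enriched peaks give ~12%
        sex-biased with a >2-fold male excess."""
        s = summarize_de_counts(13441, 558, 1282)
        assert s.pct_sex_biased == pytest.approx(12.04, abs=0.05)
        assert s.me_fe_ratio == pytest.approx(2.297, abs=0.005)
        assert s.me_fe_ratio > 2

    def test_no_sex_bias_sentinel(self):
        s = summarize_de_counts(10, 0, 0)
        assert s.pct_sex_biased == 0.0
        assert np.isnan(s.me_fe_ratio)

    @settings(deadline=None, max_examples=100)
    @given(
        st.integers(min_value=0, max_value=10**6),
        st.integers(min_value=0, max_value=10**5),
        st.integers(min_value=0, max_value=10**5),
    )
    def test_matches_direct_arithmetic(self, n0, nf, nm):
        if n0 + nf + nm == 0:
            with pytest.raises(ValueError):
                summarize_de_counts(n0, nf, nm)
            return
        s = summarize_de_counts(n0, nf, nm)
        assert s.pct_sex_biased == pytest.approx(100 * (nf + nm) / (n0 + nf + nm))
        if nf:
            assert s.me_fe_ratio == pytest.approx(nm / nf)

    def test_table_interface(self, toy_genome):
        peaks = IntervalSet(
            ["2L"] * 6, range(0, 60, 10), range(5, 65, 10), genome=toy_genome
        )
        table = DEGroupTable(peaks, ["nonDE"] * 4 + ["FE", "ME"])
        s = debias_summary(table)
        assert (s.n_nonDE, s.n_FE, s.n_ME) == (4, 1, 1)


class TestDeChromosomeProfile:
    def test_all_me_on_x(self, toy_genome):
        peaks = IntervalSet(
            ["X", "X", "2L"], [0, 100, 0], [10, 110, 10], genome=toy_genome
        )
        table = DEGroupTable(peaks, ["ME", "ME", "nonDE"])
        prof = de_chromosome_profile(table, toy_genome)
        assert prof["ME"]["x_fraction"] == 1.0
        assert "FE" not in prof  # empty group omitted

    def test_me_on_x_fraction_recovered(self):
        from rloopkit import SyntheticConfig, generate

        ds = generate(SyntheticConfig(seed=21, n_peaks=12000))
        prof = de_chromosome_profile(ds.de_labels, ds.genome)
        # n_ME ~ 1000 at this peak count; binomial tolerance +-0.05
        assert prof["ME"]["x_fraction"] == pytest.approx(0.45, abs=0.05)

    def test_length_proportional_group_rarely_significant(self, rng):
        from rloopkit.simulate import generate_null_peaks

        g = GenomeLayout(
            (("2L", 1_000_000), ("2R", 1_000_000), ("X", 600_000)),
        )
        ok = 0
        for seed in range(60):
            peaks = generate_null_peaks(g, 200, seed=seed)
            table = DEGroupTable(peaks, ["FE"] * len(peaks))
            prof = de_chromosome_profile(table, g)
            ok += prof["FE"]["p_binom"] > 0.05
        assert ok >= 54  # >= 90%


class TestScanMotif:
    def test_absent_motif(self):
        hits = scan_motif({"c": "GGGGGG"}, MotifModel("ACGT", "m"))
        assert len(hits) == 0

    def test_overlapping_matches_reported(self):
        hits = scan_motif({"c": "AAAA"}, MotifModel("AA", "m"), both_strands=False)
        assert len(hits) == 3

    def test_palindromic_position_counted_once(self):
        # "AT" is its own reverse complement
        hits = scan_motif({"c": "ATAT"}, MotifModel("AT", "m"), both_strands=True)
        starts = sorted(int(s) for s in hits.starts)
        assert starts == [0, 2]

    def test_reverse_complement_found_on_minus(self):
        hits = scan_motif({"c": "TTTCGCCTT"}, MotifModel("AAGGCGAAA", "m"))
        assert len(hits) == 1
        assert list(hits.strands) == ["-"]

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            MotifModel("ACGU", "rna")

    def test_matches_sliding_window_oracle(self, rng):
        bases = np.array(list("ACGT"))
        motifs = ["CWCC", "AAR", "GNTC", "CACA", "SWS"]
        for i in range(100):
            seq = "".join(rng.choice(bases, size=int(rng.integers(50, 400))))
            motif = motifs[i % len(motifs)]
            got = scan_motif({"c": seq}, MotifModel(motif, "m"))
            got_keys = {(c, int(s), int(e))
                        for c, s, e in zip(got.chroms, got.starts, got.ends)}
            assert got_keys == brute_scan_motif({"c": seq}, motif)


class TestMotifDensityRatio:
    def _genome(self):
        return GenomeLayout((("A", 1_000_000), ("X", 1_000_000)))

    def test_equal_density_zero_log2(self):
        g = self._genome()
        hits = IntervalSet(["A"] * 100 + ["X"] * 100, [0] * 200, [10] * 200)
        log2r, _ = motif_density_ratio(hits, g)
        assert log2r == pytest.approx(0.0)

    def test_constructed_1p5_fold(self):
        from conftest import brute_binom_two_sided

        g = self._genome()
        hits = IntervalSet(["X"] * 150 + ["A"] * 100, [0] * 250, [10] * 250)
        log2r, p = motif_density_ratio(hits, g)
        assert log2r == pytest.approx(np.log2(1.5), abs=1e-12)
        assert p == pytest.approx(brute_binom_two_sided(150, 250, 0.5), rel=1e-8)

    def test_antisymmetric_under_x_swap(self):
        g1 = GenomeLayout((("A", 1_000_000), ("X", 1_000_000)),
                          x_chroms=frozenset({"X"}))
        g2 = GenomeLayout((("A", 1_000_000), ("X", 1_000_000)),
                          x_chroms=frozenset({"A"}))
        hits = IntervalSet(["X"] * 130 + ["A"] * 70, [0] * 200, [10] * 200)
        r1, _ = motif_density_ratio(hits, g1)
        r2, _ = motif_density_ratio(hits, g2)
        assert r1 == pytest.approx(-r2)

    def test_one_sided_zero_gives_sentinel(self):
        g = self._genome()
        hits = IntervalSet(["X"] * 10, [0] * 10, [10] * 10)
        log2r, p = motif_density_ratio(hits, g)
        assert np.isnan(log2r) and np.isnan(p)

    def test_planted_x_enrichment_recovered(self):
        """Synthetic data plants 1.4-fold X motif density; with >= 2000
        total hits the estimated log2 ratio lands within +-0.15."""
        from rloopkit import SyntheticConfig, generate, scan_motif

        cfg = SyntheticConfig(
            seed=31,
            motifs=(("dense", "GGCGAAGGAG"),),
            motif_density_per_mb=1600.0,
        )
        ds = generate(cfg)
        hits = scan_motif(ds.sequence, MotifModel("GGCGAAGGAG", "dense"))
        assert len(hits) >= 2000
        log2r, p = motif_density_ratio(hits, ds.genome)
        assert log2r == pytest.approx(np.log2(1.4), abs=0.15)


class TestLabelGenes:
    def _setup(self, toy_genome):
        genes = IntervalSet(
            ["2L", "2L", "X"], [0, 1000, 0], [500, 1500, 500],
            names=["g1", "g2", "g3"], genome=toy_genome,
        )
        peaks = IntervalSet(
            ["2L", "2L", "2L"], [10, 20, 1100], [15, 30, 1110], genome=toy_genome
        )
        return genes, peaks

    def test_no_peak_gene_is_no_r_loop(self, toy_genome):
        genes, peaks = self._setup(toy_genome)
        table = DEGroupTable(peaks, ["nonDE"] * 3)
        out = label_genes(genes, table)
        assert dict(zip(out.intervals.names, out.labels))["g3"] == "no_R_loop"

    def test_fe_precedence_over_nonde(self, toy_genome):
        genes, peaks = self._setup(toy_genome)
        table = DEGroupTable(peaks, ["FE", "nonDE", "nonDE"])
        out = label_genes(genes, table)
        labels = dict(zip(out.intervals.names, out.labels))
        assert labels["g1"] == "FE"
        assert labels["g2"] == "nonDE"

    def test_every_gene_gets_exactly_one_label(self, toy_genome, rng):
        from conftest import random_interval_set

        genes = IntervalSet(
            ["2L"] * 20, range(0, 4000, 200),
            [s + 150 for s in range(0, 4000, 200)],
            names=[f"g{i}" for i in range(20)], genome=toy_genome,
        )
        peaks = random_interval_set(rng, toy_genome, 30)
        table = DEGroupTable(
            peaks, rng.choice(["nonDE", "FE", "ME"], size=30)
        )
        out = label_genes(genes, table)
        assert len(out.labels) == 20
        assert set(out.labels) <= {"nonDE", "FE", "ME", "no_R_loop"}

    def test_saturating_nonde_leaves_no_unlabelled(self, toy_genome):
        genes, _ = self._setup(toy_genome)
        blanket = IntervalSet.from_intervals(
            [GenomicInterval(c, 0, l) for c, l in toy_genome.entries],
            genome=toy_genome,
        )
        table = DEGroupTable(blanket, ["nonDE"] * len(blanket))
        out = label_genes(genes, table)
        assert not (out.labels == "no_R_loop").any()


class TestGroupCompare:
    def _gene_table(self, toy_genome, labels):
        n = len(labels)
        genes = IntervalSet(
            ["2L"] * n, range(0, 100 * n, 100),
            [s + 50 for s in range(0, 100 * n, 100)],
            names=[f"g{i}" for i in range(n)], genome=toy_genome,
        )
        return DEGroupTable(genes, labels, level="gene")

    def test_identical_distributions_p_one(self, toy_genome):
        table = self._gene_table(toy_genome, ["FE"] * 3 + ["ME"] * 3)
        values = {f"g{i}": float(i % 3) for i in range(6)}
        out = group_compare(values, table, [("FE", "ME")])
        assert out["p"].iloc[0] == 1.0

    def test_planted_shift_detected(self, rng):
        labels = ["nonDE"] * 300 + ["no_R_loop"] * 300
        big_genome = GenomeLayout((("2L", 100000),), x_chroms=frozenset())
        table = self._gene_table(big_genome, labels)
        values = {}
        for i in range(300):
            values[f"g{i}"] = float(rng.normal(1.0, 1.0))
        for i in range(300, 600):
            values[f"g{i}"] = float(rng.normal(0.0, 1.0))
        out = group_compare(values, table, [("nonDE", "no_R_loop")])
        assert out["p"].iloc[0] < 0.001
        assert out["median_a"].iloc[0] > out["median_b"].iloc[0]

    def test_gene_order_invariance(self, toy_genome, rng):
        labels = list(rng.choice(["FE", "ME", "nonDE"], size=30))
        table = self._gene_table(toy_genome, labels)
        values = {f"g{i}": float(rng.normal()) for i in range(30)}
        out1 = group_compare(values, table, [("FE", "ME"), ("nonDE", "FE")])
        order = rng.permutation(30)
        table2 = DEGroupTable(
            table.intervals.subset(order),
            np.asarray(labels, dtype=object)[order],
            level="gene",
        )
        out2 = group_compare(values, table2, [("FE", "ME"), ("nonDE", "FE")])
        pd.testing.assert_frame_equal(out1, out2)

    def test_empty_group_skipped(self, toy_genome):
        table = self._gene_table(toy_genome, ["FE"] * 4)
        out = group_compare({f"g{i}": 1.0 for i in range(4)}, table, [("FE", "ME")])
        assert out.empty


class TestPresenceFilter:
    def test_two_of_four_kept(self):
        calls = pd.DataFrame(
            [[1, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 0], [1, 1, 1, 1]],
            index=["a", "b", "c", "d"],
        )
        kept = presence_filter(calls)
        assert list(kept) == ["a", "d"]

    def test_zero_threshold_keeps_all(self):
        calls = pd.DataFrame([[0, 0, 0, 0]], index=["a"])
        assert list(presence_filter(calls, min_present=0)) == ["a"]

    def test_non_binary_rejected(self):
        calls = pd.DataFrame([[2, 0, 0, 0]], index=["a"])
        with pytest.raises(ValueError, match="binary"):
            presence_filter(calls)

    def test_wrong_column_count_rejected(self):
        calls = pd.DataFrame([[1, 0, 1]], index=["a"])
        with pytest.raises(ValueError, match="4"):
            presence_filter(calls)
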