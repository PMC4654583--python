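"""Feature engine: combination matrix, derived features, window matrix."""

import numpy as np
import pandas as pd
import pytest

from dualmut.features import (
    ExpressionRecord,
    ReplicationSignal,
    build_combination_matrix,
    build_window_matrix,
    classify_derived_features,
    replication_class,
    segment_partition,
)
from dualmut.genome import GenomeModel
from dualmut.intervals import FeatureTrack
from dualmut.variants import VariantSet

from conftest import per_bp_mask, random_track, variants_from_positions


def germline(chrom_list, pos_list, af_list) -> VariantSet:
    return VariantSet.from_arrays(chrom_list, pos_list, "germline", af=af_list)


class TestCombinationMatrix:
    def test_toy_partition_by_hand(self):
        """A=[0,100), B=[50,150) on 200 bp -> 4 combos of 50 bp each."""
        g = GenomeModel([("chr1", 200)])
        a = FeatureTrack("A", [("chr1", 0, 100)])
        b = FeatureTrack("B", [("chr1", 50, 150)])
        cm = build_combination_matrix([a, b], VariantSet.empty(), g, min_size=0)
        got = dict(zip(cm.df["bitmask"], cm.df["total_size"]))
        assert got == {0b00: 50, 0b01: 50, 0b10: 50, 0b11: 50}

    def test_all_rare_snps_give_unit_ratio(self):
        g = GenomeModel([("chr1", 1000)])
        t = FeatureTrack("A", [("chr1", 0, 500)])
        v = germline(["chr1"] * 4, [10, 100, 600, 900], [0.001] * 4)
        cm = build_combination_matrix([t], v, g, min_size=0)
        fitted = cm.df[cm.df["n_snp"] > 0]
        assert (fitted["rare_ratio"] == 1.0).all()

    def test_matches_per_bp_oracle(self, rng):
        """Random 100 kb instance: (bitmask, size, counts) equal a per-bp scan."""
        g = GenomeModel([("chr1", 100_000)])
        tracks = [random_track(rng, g, name=f"t{k}", n=30, max_len=3000) for k in range(4)]
        coding = random_track(rng, g, name="coding", n=10, max_len=2000)
        pos = np.sort(rng.choice(100_000, size=2_000, replace=False))
        af = rng.uniform(0, 0.5, size=2_000)
        v = germline(["chr1"] * 2_000, pos, af)
        cm = build_combination_matrix(tracks, v, g, coding_mask=coding, min_size=0)

        masks = np.zeros(100_000, dtype=np.int64)
        for k, t in enumerate(tracks):
            masks |= per_bp_mask(t, "chr1", 100_000).astype(np.int64) << k
        analyzed = ~per_bp_mask(coding, "chr1", 100_000)
        oracle_sizes = {}
        for m in np.unique(masks[analyzed]):
            oracle_sizes[int(m)] = int(((masks == m) & analyzed).sum())
        assert dict(zip(cm.df["bitmask"], cm.df["total_size"])) == oracle_sizes

        ok = analyzed[pos]
        o_snp = {}
        o_rare = {}
        for p, a, keep in zip(pos, af, ok):
            if not keep:
                continue
            m = int(masks[p])
            o_snp[m] = o_snp.get(m, 0) + 1
            o_rare[m] = o_rare.get(m, 0) + int(a < 0.01)
        got_snp = dict(zip(cm.df["bitmask"], cm.df["n_snp"]))
        got_rare = dict(zip(cm.df["bitmask"], cm.df["n_rare"]))
        assert got_snp == {k: o_snp.get(k, 0) for k in got_snp}
        assert got_rare == {k: o_rare.get(k, 0) for k in got_rare}

    def test_conservation_and_partition_exact(self, rng):
        g = GenomeModel([("chr1", 100_000), ("chr2", 50_000)])
        tracks = [random_track(rng, g, name=f"t{k}", n=20) for k in range(3)]
        n = 1_000
        pos = rng.integers(0, 100_000, size=n)
        chroms = np.where(rng.random(n) < 0.5, "chr1", "chr2")
        pos = np.minimum(pos, np.where(chroms == "chr2", 49_999, 99_999))
        v = germline(list(chroms), pos, rng.uniform(0, 0.5, n))
        cm = build_combination_matrix(tracks, v, g, min_size=5_000)
        # partition: all analyzed bp in exactly one row (coding mask empty)
        assert cm.df["total_size"].sum() == g.total_size == cm.analyzed_bp
        # conservation over retained + dropped rows
        assert cm.df["n_rare"].sum() / cm.df["n_snp"].sum() == pytest.approx(
            cm.global_rare_fraction
        )
        assert cm.df["n_snp"].sum() == n

    def test_size_filter_drops_rows(self):
        g = GenomeModel([("chr1", 100_000)])
        t = FeatureTrack("A", [("chr1", 0, 100)])  # 100 bp combo
        cm = build_combination_matrix([t], VariantSet.empty(), g, min_size=10_000)
        assert not cm.df.loc[cm.df["bitmask"] == 1, "retained"].any()
        assert cm.dropped_summary()["n_rows_dropped"] == 1

    def test_empty_track_list_rejected(self):
        g = GenomeModel([("chr1", 1000)])
        with pytest.raises(ValueError, match="no feature tracks"):
            build_combination_matrix([], VariantSet.empty(), g)

    def test_snp_outside_genome_rejected(self):
        g = GenomeModel([("chr1", 1000)])
        t = FeatureTrack("A", [("chr1", 0, 500)])
        v = germline(["chr1"], [5_000], [0.1])
        with pytest.raises(ValueError, match="out of bounds"):
            build_combination_matrix([t], v, g)

    def test_track_order_changes_bits_not_partition(self, rng):
        g = GenomeModel([("chr1", 50_000)])
        tracks = [random_track(rng, g, name=f"t{k}", n=10) for k in range(3)]
        cm1 = build_combination_matrix(tracks, VariantSet.empty(), g, min_size=0)
        cm2 = build_combination_matrix(tracks[::-1], VariantSet.empty(), g, min_size=0)
        assert sorted(cm1.df["total_size"]) == sorted(cm2.df["total_size"])


class TestDerivedFeatures:
    def grid_track(self, name, values):
        rows = [("chr1", i * 1000, (i + 1) * 1000, v) for i, v in enumerate(values)]
        return FeatureTrack(name, rows)

    def test_gc_thresholds_strict(self):
        out = classify_derived_features({"GC": self.grid_track("GC", [0.55, 0.50, 0.30, 0.25])})
        assert out["GC_H"].intervals("chr1").tolist() == [[0, 1000]]       # 0.55 only
        assert out["GC_L"].intervals("chr1").tolist() == [[3000, 4000]]    # 0.25 only

    def test_rr_boundary_in_neither_class(self):
        out = classify_derived_features({"RR": self.grid_track("RR", [4.0, 0.5])})
        assert out["RR_H"].total_bp() == 0 and out["RR_L"].total_bp() == 0

    def test_methylation_defaults(self):
        out = classify_derived_features({"met": self.grid_track("met", [0.80, 0.30])})
        assert out["met_H"].total_bp() == 1000 and out["met_L"].total_bp() == 1000

    def test_off_grid_rejected(self):
        t = FeatureTrack("GC", [("chr1", 10, 1010, 0.4)])
        with pytest.raises(ValueError, match="grid"):
            classify_derived_features({"GC": t})


class TestReplicationClass:
    def test_early(self):
        sigs = [ReplicationSignal(2, 2, 1, 1)] * 3  # E/L = 2 in all lines
        assert replication_class(sigs) == "early"

    def test_mixed_unclassified(self):
        sigs = [ReplicationSignal(3, 0, 1, 1), ReplicationSignal(0.4, 0.4, 0.5, 0.5)]
        assert replication_class(sigs) == "unclassified"

    def test_exact_one_unclassified(self):
        assert replication_class([ReplicationSignal(1, 0, 1, 0)]) == "unclassified"

    def test_zero_denominator_unclassified(self):
        assert replication_class([ReplicationSignal(1, 1, 0, 0)]) == "unclassified"

    def test_all_late(self):
        assert replication_class([ReplicationSignal(1, 0, 2, 2)] * 2) == "late"


class TestExpression:
    def test_rpkm_formula(self):
        # 1000 reads, 2 kb exons, 10 M reads -> 1000 / (2 x 10) = 50
        r = ExpressionRecord(read_count=1000, exon_length_bp=2000, library_size=10_000_000)
        assert r.rpkm == pytest.approx(50.0)
        assert r.expression_class == "HE"

    def test_classes_strict(self):
        he = ExpressionRecord(20.0 * 2 * 10, 2000, 10_000_000)  # RPKM exactly 20
        assert he.expression_class is None
        le = ExpressionRecord(1, 2000, 10_000_000)  # RPKM 0.05
        assert le.expression_class == "LE"


class TestWindowMatrix:
    def somatic(self, chrom, pos):
        return VariantSet.from_arrays(
            [chrom] * len(pos), pos, "somatic", patient_id=["P0"] * len(pos)
        )

    def test_ten_windows_no_exclusion(self):
        g = GenomeModel([("chr1", 10_000_000)])
        t = FeatureTrack("A", [("chr1", 0, 1_000_000)])
        wm = build_window_matrix([t], self.somatic("chr1", [5]), g)
        assert len(wm.df) == 10

    def test_half_coverage_constant_column(self):
        g = GenomeModel([("chr1", 3_000_000)])
        ivs = [("chr1", i * 1_000_000, i * 1_000_000 + 500_000) for i in range(3)]
        t = FeatureTrack("A", ivs)
        wm = build_window_matrix([t], self.somatic("chr1", [5]), g)
        assert np.allclose(wm.df["A"], np.log(500_001))

    def test_mutation_counts_match_brute_force(self, rng):
        g = GenomeModel([("chr1", 5_000_000)])
        t = FeatureTrack("A", [("chr1", 0, 1_000)])
        pos = rng.integers(0, 5_000_000, size=3_000)
        wm = build_window_matrix([t], self.somatic("chr1", pos), g)
        oracle = [(
            (pos >= k * 1_000_000) & (pos < (k + 1) * 1_000_000)).sum() for k in range(5)]
        assert wm.df["n_mutations"].tolist() == oracle

    def test_excluded_window_dropped(self):
        g = GenomeModel(
            [("chr1", 5_000_000)],
            excluded=FeatureTrack("excl", [("chr1", 1_500_000, 1_600_000)]),
        )
        t = FeatureTrack("A", [("chr1", 0, 1_000)])
        wm = build_window_matrix([t], self.somatic("chr1", [5]), g)
        assert len(wm.df) == 4 and wm.n_windows_excluded == 1
        assert 1_000_000 not in wm.df["start"].tolist()

    def test_trailing_partial_window_dropped(self):
        g = GenomeModel([("chr1", 2_500_000)])
        t = FeatureTrack("A", [("chr1", 0, 1_000)])
        wm = build_window_matrix([t], self.somatic("chr1", [5]), g)
        assert len(wm.df) == 2

    def test_short_chromosome_warns(self):
        g = GenomeModel([("chr1", 2_000_000), ("chr2", 500_000)])
        t = FeatureTrack("A", [("chr1", 0, 1_000)])
        with pytest.warns(UserWarning, match="shorter"):
            wm = build_window_matrix([t], self.somatic("chr1", [5]), g)
        assert set(wm.df["chrom"]) == {"chr1"}

    def test_predictor_order_invariance(self, rng):
        g = GenomeModel([("chr1", 5_000_000)])
        tracks = [random_track(rng, g, name=f"t{k}", n=40, max_len=50_000) for k in range(3)]
        som = self.somatic("chr1", rng.integers(0, 5_000_000, size=500))
        wm1 = build_window_matrix(tracks, som, g)
        wm2 = build_window_matrix(tracks[::-1], som, g)
        for name in ("t0", "t1", "t2"):
            assert np.allclose(wm1.df[name], wm2.df[name])

    def test_value_track_window_mean(self):
        g = GenomeModel([("chr1", 2_000_000)])
        vt = FeatureTrack("rr", [("chr1", 0, 500_000, 2.0), ("chr1", 500_000, 1_000_000, 4.0)])
        wm = build_window_matrix([vt], self.somatic("chr1", [5]), g)
        # window 1 mean = 3.0 -> ln(4); window 2 uncovered -> imputed genome mean 3.0
        assert np.allclose(wm.df["rr"], np.log(4.0))


def test_segment_partition_covers_chromosome(rng):
    g = GenomeModel([("chr1", 80_000)])
    tracks = [random_track(rng, g, name=f"t{k}", n=15) for k in range(3)]
    cuts, masks = segment_partition(g, tracks, "chr1")
    assert cuts[0] == 0 and cuts[-1] == 80_000
    assert len(masks) == len(cuts) - 1
    oracle = np.zeros(80_000, dtype=np.int64)
    for k, t in enumerate(tracks):
        oracle |= per_bp_mask(t, "chr1", 80_000).astype(np.int64) << k
    expanded = np.repeat(masks, np.diff(cuts))
    assert np.array_equal(expanded, oracle)
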