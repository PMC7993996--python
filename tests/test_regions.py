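import numpy as np
import pandas as pd
import pytest

from replifate.core import Segment, empty_intervals
from replifate.regions import (classify_as, genes_exclusion_zone,
                               intersect_replicate_peaks,
                               region_mean_frequency, segments_to_intervals,
                               subset_by_mark)

from conftest import make_track


def gene(chrom, start, end, tpm):
    return dict(gene_id=f"g{start}", chrom=chrom, start=start, end=end,
                strand="+", tpm=tpm)


AS = Segment("chr1", 1_000_000, 1_060_000, "AS", delta_rfd=1.0)


class TestClassifyAs:
    def test_type1_both_borders(self):
        genes = pd.DataFrame([
            gene("chr1", 940_000, 990_000, 20.0),     # ends 10 kb left
            gene("chr1", 1_065_000, 1_120_000, 20.0)  # starts 5 kb right
        ])
        [seg] = classify_as([AS], genes)
        assert seg.as_type == "type1" and not seg.orientation_flipped

    def test_type2_left_only_flips(self):
        genes = pd.DataFrame([gene("chr1", 940_000, 990_000, 20.0)])
        [seg] = classify_as([AS], genes)
        assert seg.as_type == "type2" and seg.orientation_flipped

    def test_type2_right_only_not_flipped(self):
        genes = pd.DataFrame([gene("chr1", 1_065_000, 1_120_000, 20.0)])
        [seg] = classify_as([AS], genes)
        assert seg.as_type == "type2" and not seg.orientation_flipped

    def test_non_genic_when_gene_beyond_flank(self):
        genes = pd.DataFrame([gene("chr1", 900_000, 975_000, 20.0)])
        [seg] = classify_as([AS], genes)  # gene ends 25 kb away
        assert seg.as_type == "non_genic"

    def test_silent_neighbor_gives_genic_other(self):
        genes = pd.DataFrame([gene("chr1", 940_000, 990_000, 1.0)])
        [seg] = classify_as([AS], genes)
        assert seg.as_type == "genic_other"

    def test_partition_and_permutation_invariance(self, small_genome):
        genes, truth = small_genome
        segs = [Segment(f.chrom, f.start, f.end, "AS",
                        delta_rfd=2 * f.efficiency)
                for f in truth.features_of("IZ")]
        typed = classify_as(segs, genes)
        assert all(s.as_type is not None for s in typed)
        counts = pd.Series([s.as_type for s in typed]).value_counts()
        rng = np.random.default_rng(0)
        shuffled = [segs[i] for i in rng.permutation(len(segs))]
        counts2 = pd.Series(
            [s.as_type for s in classify_as(shuffled, genes)]).value_counts()
        assert counts.to_dict() == counts2.to_dict()

    def test_planted_types_recovered(self, small_genome):
        genes, truth = small_genome
        for f in truth.features_of("IZ"):
            [seg] = classify_as(
                [Segment(f.chrom, f.start, f.end, "AS", delta_rfd=1.0)],
                genes)
            assert seg.as_type == f.as_type, f"IZ at {f.start}"


class TestSubsetByMark:
    def _track(self):
        # mean 1.0, sd 0.2 by construction
        rng = np.random.default_rng(1)
        v = rng.normal(size=2000)
        v = (v - v.mean()) / v.std() * 0.2 + 1.0
        return make_track(v, bin_width=10_000)

    def _seg_at(self, value, track):
        # interval covering bins manually set to `value`
        t = track.copy()
        t.data["chr1"][100:110] = value
        return Segment("chr1", 1_000_000, 1_100_000, "AS"), t

    @pytest.mark.parametrize("value,expect", [
        (1.4, "high"), (0.9, "low"), (1.1, "neither")])
    def test_rules(self, value, expect):
        seg, t = self._seg_at(value, self._track())
        high, low, neither = subset_by_mark([seg], t)
        got = ("high" if high else "low" if low else "neither")
        assert got == expect

    def test_partition_and_monotonicity(self):
        rng = np.random.default_rng(2)
        t = self._track()
        segs = [Segment("chr1", int(s), int(s) + 50_000, "AS")
                for s in rng.integers(0, 19_000_000, 40)]
        high, low, neither = subset_by_mark(segs, t)
        assert len(high) + len(low) + len(neither) == len(segs)
        high2, _, _ = subset_by_mark(segs, t, sd_multiple=2.5)
        assert set((s.pos_5p) for s in high2) <= set(s.pos_5p for s in high)


class TestPeakIntersect:
    def _iv(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def test_identical_sets(self):
        a = self._iv([("chr1", 0, 100), ("chr1", 500, 700)])
        out = intersect_replicate_peaks([a, a.copy(), a.copy()])
        assert out.values.tolist() == a.values.tolist()

    def test_disjoint_set_empties(self):
        a = self._iv([("chr1", 0, 100)])
        b = self._iv([("chr1", 200, 300)])
        assert len(intersect_replicate_peaks([a, b])) == 0

    def test_empty_input_empties(self):
        a = self._iv([("chr1", 0, 100)])
        assert len(intersect_replicate_peaks([a, empty_intervals()])) == 0

    def test_matches_sweep_oracle(self):
        rng = np.random.default_rng(3)

        def random_set():
            starts = np.sort(rng.choice(10_000, 30, replace=False)) * 10
            return self._iv([("chr1", int(s), int(s + rng.integers(10, 400)))
                             for s in starts])

        sets = [random_set() for _ in range(3)]
        got = intersect_replicate_peaks(sets)
        # oracle: brute-force pairwise overlap scan
        keep = []
        for _, s, e in sets[0].itertuples(index=False):
            if all(any(oe > s and os < e for _, os, oe in
                       other.itertuples(index=False))
                   for other in sets[1:]):
                keep.append(("chr1", s, e))
        from replifate.core import merge_intervals
        expect = merge_intervals(self._iv(keep)) if keep else empty_intervals()
        assert got.values.tolist() == expect.values.tolist()


class TestRegionMeanFrequency:
    def test_planted_ratio(self):
        v = np.full(3000, np.nan)
        v[:1000] = 1.4
        v[1000:] = 1.0
        t = make_track(v, bin_width=10_000)
        classes = {
            "early": pd.DataFrame([("chr1", 0, 10_000_000)],
                                  columns=["chrom", "start", "end"]),
            "late": pd.DataFrame([("chr1", 10_000_000, 30_000_000)],
                                 columns=["chrom", "start", "end"])}
        res = region_mean_frequency(classes, t, ratio_between=("early", "late"))
        assert res["ratio"] == pytest.approx(1.40)

    def test_identical_classes_ratio_one(self):
        t = make_track(np.random.default_rng(4).uniform(0.5, 1.5, 1000),
                       bin_width=10_000)
        iv = pd.DataFrame([("chr1", 0, 10_000_000)],
                          columns=["chrom", "start", "end"])
        res = region_mean_frequency({"a": iv, "b": iv.copy()}, t,
                                    ratio_between=("a", "b"))
        assert res["ratio"] == pytest.approx(1.0)

    def test_exclusion_drops_gene_bins(self):
        v = np.ones(1000)
        v[:50] = 100.0  # gene region bins, must be excluded
        t = make_track(v, bin_width=10_000)
        genes = pd.DataFrame([gene("chr1", 0, 490_000, 10.0)])
        iv = pd.DataFrame([("chr1", 0, 10_000_000)],
                          columns=["chrom", "start", "end"])
        res = region_mean_frequency({"a": iv}, t,
                                    exclusion=genes_exclusion_zone(genes))
        assert res["classes"].loc["a", "mean"] == pytest.approx(1.0)

    def test_empty_class_errors(self):
        t = make_track(np.ones(100), bin_width=10_000)
        iv = pd.DataFrame([("chr9", 0, 1_000_000)],
                          columns=["chrom", "start", "end"])
        with pytest.raises(ValueError, match="no qualifying"):
            region_mean_frequency({"a": iv}, t)
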