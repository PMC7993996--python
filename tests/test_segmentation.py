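import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from replifate.segmentation import (ConvexitySettings, detect_constant_rfd,
                                    detect_rtds, detect_segments,
                                    filter_segments, smooth_convexity,
                                    smooth_rt)
from replifate.core import Segment

from conftest import make_track

W = 1000
SET = ConvexitySettings()


def logistic_step(n_bins, center_bin, lo, hi, scale_bins):
    x = np.arange(n_bins)
    return lo + (hi - lo) / (1 + np.exp(-(x - center_bin) / scale_bins))


class TestSmoothConvexity:
    def test_constant_rfd_gives_zero(self):
        c = smooth_convexity(make_track(np.full(2000, 0.4)), SET)
        v = c.data["chr1"]
        assert np.nanmax(np.abs(v)) < 1e-12

    def test_linear_ramp_interior_is_zero(self):
        ramp = np.linspace(-1, 1, 4000)
        c = smooth_convexity(make_track(ramp), SET).data["chr1"]
        interior = c[1000:3000]
        assert np.nanmax(np.abs(interior)) < 1e-9

    def test_logistic_upshift_matches_finite_difference_oracle(self):
        n, x0 = 4000, 2000
        prof = logistic_step(n, x0, -0.8, 0.8, 8)
        c = smooth_convexity(make_track(prof), SET).data["chr1"]
        # oracle: second difference of the Gaussian-smoothed profile
        sm = gaussian_filter1d(prof, sigma=32, mode="nearest")
        d2 = np.gradient(np.gradient(sm))
        pos_o, neg_o = np.nanargmax(d2), np.nanargmin(d2)
        pos_c, neg_c = np.nanargmax(c), np.nanargmin(c)
        assert abs(pos_c - pos_o) <= 1 and abs(neg_c - neg_o) <= 1
        assert pos_c < x0 < neg_c
        # antisymmetric extrema
        assert np.nanmax(c) == pytest.approx(-np.nanmin(c), rel=0.05)

    def test_short_chromosome_warns_all_missing(self):
        with pytest.warns(UserWarning, match="kernel"):
            c = smooth_convexity(make_track(np.zeros(100)), SET)
        assert np.isnan(c.data["chr1"]).all()

    def test_long_gap_splits_domains(self):
        v = np.zeros(4000)
        v[1500:1520] = np.nan  # 20 > max_gap_bins
        c = smooth_convexity(make_track(v), SET).data["chr1"]
        assert np.isnan(c[1500:1520]).all()

    def test_bin_width_guard(self):
        with pytest.raises(ValueError, match="sigma/8"):
            smooth_convexity(make_track(np.zeros(100), bin_width=10_000), SET)


class TestDetectSegments:
    def test_single_upshift_yields_one_as(self):
        prof = logistic_step(6000, 3000, -0.5, 0.5, 10)
        t = make_track(prof)
        asl, dsl = detect_segments(smooth_convexity(t, SET), t, SET)
        assert len(asl) == 1 and len(dsl) == 0
        seg = asl[0]
        assert seg.pos_5p < 3000 * W < seg.pos_3p
        assert seg.delta_rfd == pytest.approx(1.0, abs=0.05)

    def test_flat_profile_yields_nothing(self):
        t = make_track(np.zeros(4000))
        asl, dsl = detect_segments(smooth_convexity(t, SET), t, SET)
        assert asl == [] and dsl == []

    def test_mirrored_profile_swaps_as_and_ds(self, small_rfd):
        conv = smooth_convexity(small_rfd, SET)
        asl, dsl = detect_segments(conv, small_rfd, SET)
        neg = small_rfd.copy()
        neg.data["chr1"] = -neg.data["chr1"]
        asl2, dsl2 = detect_segments(smooth_convexity(neg, SET), neg, SET)
        assert [(s.pos_5p, s.pos_3p) for s in asl] == \
               [(s.pos_5p, s.pos_3p) for s in dsl2]
        assert [(s.pos_5p, s.pos_3p) for s in dsl] == \
               [(s.pos_5p, s.pos_3p) for s in asl2]

    def test_as_ds_alternate_and_never_overlap(self, small_rfd):
        conv = smooth_convexity(small_rfd, SET)
        asl, dsl = detect_segments(conv, small_rfd, SET)
        merged = sorted(asl + dsl, key=lambda s: s.pos_5p)
        for a, b in zip(merged, merged[1:]):
            assert a.pos_3p <= b.pos_5p
            assert a.kind != b.kind

    def test_raising_threshold_never_adds_segments(self, small_rfd):
        counts = []
        for mult in (1.0, 2.0, 4.0, 8.0):
            s = ConvexitySettings(threshold_value=mult)
            asl, dsl = detect_segments(smooth_convexity(small_rfd, s),
                                       small_rfd, s)
            counts.append(len(asl) + len(dsl))
        assert counts == sorted(counts, reverse=True)


class TestFilterSegments:
    def test_strict_length_cutoff(self):
        short = Segment("chr1", 0, 19_999, "AS", delta_rfd=0.6)
        exact = Segment("chr1", 0, 20_000, "AS", delta_rfd=0.6)
        longer = Segment("chr1", 0, 20_001, "AS", delta_rfd=0.6)
        assert filter_segments([short, exact, longer]) == [longer]

    def test_strict_delta_cutoff(self):
        seg = Segment("chr1", 0, 30_000, "AS", delta_rfd=0.5)
        assert filter_segments([seg]) == []

    def test_abs_mode_keeps_descending(self):
        ds = Segment("chr1", 0, 30_000, "DS", delta_rfd=-0.9)
        assert filter_segments([ds]) == []
        assert filter_segments([ds], use_abs=True) == [ds]


class TestConstantRfd:
    def test_urr_at_350kb(self):
        v = np.zeros(1000)
        v[100:450] = 0.9
        urr = detect_constant_rfd(make_track(v), "URR")
        assert [(s.pos_5p, s.pos_3p) for s in urr] == [(100_000, 450_000)]

    def test_urr_too_short(self):
        v = np.zeros(1000)
        v[100:350] = 0.9
        assert detect_constant_rfd(make_track(v), "URR") == []

    def test_nrr_broken_by_single_bin(self):
        v = np.full(1000, 0.5)
        v[100:700] = 0.05
        v[400] = 0.2
        assert detect_constant_rfd(make_track(v), "NRR") == []

    def test_true_profile_matches_planted(self, small_genome, small_rfd):
        _, truth = small_genome
        for mode in ("URR", "NRR"):
            called = detect_constant_rfd(small_rfd, mode)
            planted = truth.features_of(mode)
            assert len(called) == len(planted)
            for c, p in zip(called, sorted(planted, key=lambda f: f.start)):
                assert abs(c.pos_5p - p.start) <= small_rfd.bin_width
                assert abs(c.pos_3p - p.end) <= small_rfd.bin_width


class TestSmoothRt:
    def test_constant_unchanged(self):
        t = make_track(np.full(100, 1.7), bin_width=10_000)
        out = smooth_rt(t)
        np.testing.assert_allclose(out.data["chr1"], 1.7)

    def test_single_spike_spreads_over_window(self):
        v = np.zeros(100)
        v[50] = 10.0
        out = smooth_rt(make_track(v, bin_width=10_000)).data["chr1"]
        # window i-5..i+4 covers the spike for i in 46..55
        np.testing.assert_allclose(out[46:56], 1.0)
        assert out[45] == 0.0 and out[56] == 0.0

    def test_matches_moving_average_oracle(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=300)
        v[rng.choice(300, 20, replace=False)] = np.nan
        out = smooth_rt(make_track(v, bin_width=10_000)).data["chr1"]
        for i in range(300):
            window = v[max(0, i - 5):i + 5]
            expect = (np.nan if np.isnan(window).all()
                      else np.nanmean(window))
            if np.isnan(expect):
                assert np.isnan(out[i])
            else:
                assert out[i] == pytest.approx(expect, abs=1e-12)


class TestDetectRtds:
    def test_constant_early_chromosome(self):
        t = make_track(np.full(200, 2.0), bin_width=10_000)
        early, late = detect_rtds(t)
        assert [(s.pos_5p, s.pos_3p) for s in early] == [(0, 2_000_000)]
        assert late == []

    def test_threshold_is_strict(self):
        t = make_track(np.full(200, 1.6), bin_width=10_000)
        early, _ = detect_rtds(t)
        assert early == []

    def test_merge_gap_option(self):
        v = np.full(100, -3.0)
        v[10:20] = 2.0
        v[22:30] = 2.0
        t = make_track(v, bin_width=10_000)
        early, _ = detect_rtds(t)
        assert len(early) == 2
        merged, _ = detect_rtds(t, merge_gap=30_000)
        assert len(merged) == 1
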