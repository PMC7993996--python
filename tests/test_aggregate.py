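import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from replifate.aggregate import (anova_tukey, border_profile,
                                 gene_metaprofile, ks_z, rt_decile_hist2d,
                                 welch_t_one_sided)
from replifate.core import Segment

from conftest import make_track


def seg(a, b, flipped=False):
    return Segment("chr1", a, b, "AS", delta_rfd=1.0,
                   orientation_flipped=flipped)


class TestBorderProfile:
    def test_constant_tracks_flat_at_one(self):
        t = make_track(np.full(1000, 2.0))
        segs = [seg(300_000, 400_000), seg(600_000, 700_000)]
        df, skipped = border_profile(segs, t, t.copy())
        assert skipped == 0
        np.testing.assert_allclose(df["profile"], 1.0)
        np.testing.assert_allclose(df["sem"], 0.0)

    def test_single_locus_equals_locus_ratio(self):
        rng = np.random.default_rng(0)
        s = make_track(rng.uniform(0.5, 2.0, 1000))
        i = make_track(rng.uniform(0.5, 2.0, 1000))
        df, _ = border_profile([seg(300_000, 400_000)], s, i)
        b = 300
        offs = df["offset_bp"].to_numpy() // 1000
        expect = s.data["chr1"][b + offs] / i.data["chr1"][b + offs]
        np.testing.assert_allclose(df["profile"], expect, rtol=1e-12)

    def test_planted_interior_enrichment_recovered(self):
        rng = np.random.default_rng(1)
        n = 5000
        segs = [seg(a, a + 60_000) for a in range(300_000, 4_500_000,
                                                  300_000)]
        base = rng.normal(1.0, 0.05, n)
        for s_ in segs:
            base[s_.pos_5p // 1000: s_.pos_3p // 1000] *= 1.3
        sample = make_track(base)
        inp = make_track(np.full(n, 1.0))
        df, _ = border_profile(segs, sample, inp)
        inside = df[df["offset_bp"] >= 2000]["profile"].mean()
        outside = df[df["offset_bp"] <= -10_000]["profile"].mean()
        assert inside == pytest.approx(1.3, abs=0.05)
        assert outside == pytest.approx(1.0, abs=0.05)

    def test_right_border_mirrors(self):
        v = np.ones(1000)
        v[400:] = 5.0  # signal beyond the right border
        t = make_track(v)
        df, _ = border_profile([seg(300_000, 400_000)], t, None,
                               upstream=20_000, inside=10_000, align="right")
        # offset -1 kb is just outside the right border
        row = df[df["offset_bp"] == -1000].iloc[0]
        assert row["mean_sample"] == 5.0
        row_in = df[df["offset_bp"] == 5000].iloc[0]
        assert row_in["mean_sample"] == 1.0

    def test_flipped_segment_swaps_borders(self):
        v = np.ones(1000)
        v[:350] = 3.0  # signal left of the (physical) left border
        t = make_track(v)
        plain, _ = border_profile([seg(350_000, 450_000)], t, None,
                                  align="left")
        flipped, _ = border_profile([seg(350_000, 450_000, flipped=True)], t,
                                    None, align="right")
        # the flipped right border is the physical left border
        np.testing.assert_allclose(plain["mean_sample"],
                                   flipped["mean_sample"])

    def test_short_segments_skipped(self):
        t = make_track(np.ones(100))
        df, skipped = border_profile([seg(10_000, 25_000),
                                      seg(30_000, 80_000)], t, None)
        assert skipped == 1


class TestGeneMetaprofile:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=[
            "gene_id", "chrom", "start", "end", "strand", "tpm",
            "activity_class"])

    def test_minus_strand_orientation(self):
        # signal upstream of a minus-strand gene (genomically right of its
        # TSS = end) must appear at negative offsets after orientation
        v = np.ones(1000)
        v[505:520] = 9.0  # 5-20 kb right of TSS at 505 kb
        t = make_track(v)
        genes = self._genes(
            [("g1", "chr1", 400_000, 505_000, "-", 50.0, "high")])
        prof = gene_metaprofile(genes, t, None, align="TSS")["high"]
        up = prof[prof["offset_bp"] == -10_000].iloc[0]["profile"]
        down = prof[prof["offset_bp"] == 10_000].iloc[0]["profile"]
        assert up == 9.0 and down == 1.0

    def test_constant_signal_flat_profiles(self):
        t = make_track(np.full(1000, 1.7))
        genes = self._genes(
            [("g1", "chr1", 300_000, 350_000, "+", 50.0, "high"),
             ("g2", "chr1", 600_000, 660_000, "-", 50.0, "high")])
        prof = gene_metaprofile(genes, t, t.copy(), align="TTS")["high"]
        np.testing.assert_allclose(prof["profile"], 1.0)

    def test_isolation_filter(self):
        t = make_track(np.ones(1000))
        genes = self._genes(
            [("g1", "chr1", 300_000, 350_000, "+", 50.0, "high"),
             ("g2", "chr1", 360_000, 420_000, "+", 50.0, "high"),
             ("g3", "chr1", 700_000, 760_000, "+", 1.0, "no")])
        with pytest.warns(UserWarning, match="no eligible"):
            prof = gene_metaprofile(genes, t, None)
        assert set(prof) == {"no"}  # g1/g2 are within 15 kb of each other


class TestRtDecileHist2d:
    def test_constant_chip_point_mass_columns(self):
        rng = np.random.default_rng(2)
        chip = make_track(np.ones(5000), bin_width=10_000)
        rt = make_track(rng.normal(size=5000), bin_width=10_000)
        res = rt_decile_hist2d(chip, rt)
        sums = np.nansum(res["hist"], axis=0)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        assert (np.nanmax(res["hist"], axis=0) == 1.0).all()

    def test_rank_signal_monotone_column_means(self):
        rng = np.random.default_rng(3)
        rt_v = rng.normal(size=5000)
        chip_v = sps.rankdata(rt_v) / 5000.0
        res = rt_decile_hist2d(make_track(chip_v, bin_width=10_000),
                               make_track(rt_v, bin_width=10_000))
        means = res["column_stats"]["mean"].to_numpy()
        assert (np.diff(means) > 0).all()

    def test_restriction_mask_limits_bins(self):
        rng = np.random.default_rng(4)
        chip = make_track(rng.uniform(0, 2, 5000), bin_width=10_000)
        rt = make_track(rng.normal(size=5000), bin_width=10_000)
        mask = {"chr1": np.zeros(5000, dtype=bool)}
        mask["chr1"][:500] = True
        res = rt_decile_hist2d(chip, rt, restriction_mask=mask)
        assert res["n_bins"] == 500


class TestKsZ:
    def test_identical_samples(self):
        r = ks_z([1, 2, 3], [1, 2, 3])
        assert r.d == 0.0 and r.z == 0.0

    def test_fully_separated(self):
        r = ks_z([1, 2, 3], [10, 11, 12, 13])
        assert r.d == 1.0
        assert r.z == pytest.approx(np.sqrt(3 * 4 / 7))

    def test_z_identity(self):
        rng = np.random.default_rng(5)
        r = ks_z(rng.normal(size=40), rng.normal(0.5, 1, 60))
        assert r.z == pytest.approx(r.d * np.sqrt(40 * 60 / 100), rel=1e-12)

    def test_matches_ecdf_grid_oracle(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=37)
        b = rng.normal(0.3, 1.2, size=53)
        grid = np.concatenate([a, b])
        ecdf_a = (a[:, None] <= grid[None, :]).mean(axis=0)
        ecdf_b = (b[:, None] <= grid[None, :]).mean(axis=0)
        d_oracle = np.abs(ecdf_a - ecdf_b).max()
        assert ks_z(a, b).d == pytest.approx(d_oracle, abs=1e-12)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ks_z([], [1.0])


class TestWelch:
    def test_identical_groups_half(self):
        a = np.arange(10.0)
        t, p = welch_t_one_sided(a, a.copy(), "greater")
        assert p == pytest.approx(0.5)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=30)
        _, p = welch_t_one_sided(a, a + 50, "less")
        assert p < 1e-6

    def test_zero_variance_convention(self):
        t, p = welch_t_one_sided([1.0, 1.0, 1.0], [1.0, 1.0], "greater")
        assert (t, p) == (0.0, 0.5)


class TestAnovaTukey:
    def test_shifted_group_significant(self):
        rng = np.random.default_rng(8)
        g1 = rng.normal(size=30)
        g2 = rng.normal(size=30)
        g3 = rng.normal(5.0, 1.0, size=30)
        res = anova_tukey([g1, g2, g3])
        assert res["p"] < 1e-10
        assert res["tukey_p"][0, 2] < 1e-6
        assert res["tukey_p"][1, 2] < 1e-6

    def test_identical_pair_not_significant(self):
        rng = np.random.default_rng(9)
        g = rng.normal(size=40)
        res = anova_tukey([g, g.copy(), g + 3])
        assert res["tukey_p"][0, 1] > 0.99

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([[1.0], [1.0, 2.0]])
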