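"""Locus-aligned aggregate profiles, RT-decile histograms and statistics.

Aggregate ChIP profiles are built from mean-normalized (but not yet
input-divided) 1-kb tracks: the sample and input tracks are averaged across
loci separately and the ratio of the mean profiles is taken afterwards
("input normalization after averaging"); uncertainty bands are ±2 SEM of
the sample track propagated through that division.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import BinnedTrack, KsResult, Segment

__all__ = [
    "border_profile",
    "gene_metaprofile",
    "rt_decile_hist2d",
    "ks_z",
    "welch_t_one_sided",
    "anova_tukey",
]


def _locus_rows(track: BinnedTrack, chrom: str, idx: np.ndarray) -> np.ndarray:
    """Track values at bin indices, NaN outside the chromosome."""
    v = track.data[chrom]
    out = np.full(len(idx), np.nan)
    ok = (idx >= 0) & (idx < len(v))
    out[ok] = v[idx[ok]]
    return out


def _nan_sem(mat: np.ndarray) -> np.ndarray:
    n = np.isfinite(mat).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(mat, axis=0, ddof=1)
    return np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)


def border_profile(
    segments: Sequence[Segment],
    sample_track: BinnedTrack,
    input_track: BinnedTrack | None,
    upstream: int = 50_000,
    inside: int = 10_000,
    align: str = "left",
    respect_orientation: bool = True,
    ratio_of_means: bool = True,
) -> tuple[pd.DataFrame, int]:
    """Aggregate signal around segment borders, outside-to-inside.

    Offsets run from ``-upstream`` (outside the segment) to ``+inside``
    (within it) relative to the aligned border; for the right border the
    axis is mirrored so positive offsets always point into the segment.
    Segments flipped by type-2 orientation swap borders and mirror when
    ``respect_orientation``. Segments not longer than ``2*inside`` are
    skipped; their count is returned alongside the profile table.

    With ``ratio_of_means`` (default, matching the aggregate convention)
    the profile is mean(sample)/mean(input) per offset; otherwise the mean
    of per-locus ratios.
    """
    if align not in ("left", "right"):
        raise ValueError("align must be 'left' or 'right'")
    w = sample_track.bin_width
    if input_track is not None and not sample_track.congruent(input_track):
        raise ValueError("sample and input tracks are not congruent")
    offs = np.arange(-(upstream // w), inside // w)
    sample_rows, input_rows = [], []
    skipped = 0
    for seg in segments:
        if seg.length <= 2 * inside:
            skipped += 1
            continue
        flipped = respect_orientation and seg.orientation_flipped
        # positive offsets always point into the segment; the right border
        # (and the mirrored left border of a flipped segment) is traversed
        # outward-to-inward from the segment's physical right edge
        mirror = (align == "right") != flipped
        if mirror:
            idx = (seg.pos_3p // w - 1) - offs
        else:
            idx = seg.pos_5p // w + offs
        sample_rows.append(_locus_rows(sample_track, seg.chrom, idx))
        if input_track is not None:
            input_rows.append(_locus_rows(input_track, seg.chrom, idx))
    if not sample_rows:
        raise ValueError("no usable segments")
    S = np.vstack(sample_rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_s = np.nanmean(S, axis=0)
    sem_s = _nan_sem(S)
    if input_track is None:
        profile, sem = mean_s, sem_s
        mean_i = np.full_like(mean_s, np.nan)
    else:
        I = np.vstack(input_rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_i = np.nanmean(I, axis=0)
            if ratio_of_means:
                profile = mean_s / mean_i
                sem = sem_s / mean_i
            else:
                R = S / I
                profile = np.nanmean(R, axis=0)
                sem = _nan_sem(R)
    df = pd.DataFrame({
        "offset_bp": offs * w,
        "mean_sample": mean_s,
        "mean_input": mean_i,
        "profile": profile,
        "sem": sem,
        "n": np.isfinite(S).sum(axis=0),
    })
    return df, skipped


def gene_metaprofile(
    genes: pd.DataFrame,
    sample_track: BinnedTrack,
    input_track: BinnedTrack | None,
    min_length: int = 30_000,
    isolation: int = 15_000,
    window: int = 30_000,
    align: str = "TSS",
    class_column: str = "activity_class",
) -> dict[str, pd.DataFrame]:
    """Strand-oriented aggregate profiles around TSS or TTS per activity class.

    Eligible genes are longer than ``min_length`` with no other gene within
    ``isolation`` bp. Profiles cover a ``window``-bp span centered on the
    alignment site, oriented 5'→3' by gene strand, with input division
    after averaging. Classes without eligible genes are omitted with a
    warning.
    """
    if align not in ("TSS", "TTS"):
        raise ValueError("align must be 'TSS' or 'TTS'")
    w = sample_track.bin_width
    half = window // 2
    offs = np.arange(-(half // w), half // w)
    lengths = genes["end"] - genes["start"]
    eligible = lengths > min_length
    # isolation: any other gene closer than `isolation` disqualifies
    for i in np.flatnonzero(eligible.to_numpy()):
        g = genes.iloc[i]
        others = genes[(genes["chrom"] == g["chrom"]) & (genes.index != genes.index[i])]
        if (((others["end"] > g["start"] - isolation)
             & (others["start"] < g["end"] + isolation)).any()):
            eligible.iloc[i] = False
    out: dict[str, pd.DataFrame] = {}
    for cls, grp in genes[eligible].groupby(class_column):
        sample_rows, input_rows = [], []
        for _, g in grp.iterrows():
            plus = g["strand"] == "+"
            if (align == "TSS") == plus:
                anchor, mirrored = int(g["start"]), not plus
            else:
                anchor, mirrored = int(g["end"]), not plus
            if not mirrored:
                idx = anchor // w + offs
            else:
                idx = (anchor - 1) // w - offs
            sample_rows.append(_locus_rows(sample_track, g["chrom"], idx))
            if input_track is not None:
                input_rows.append(_locus_rows(input_track, g["chrom"], idx))
        S = np.vstack(sample_rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_s = np.nanmean(S, axis=0)
        sem_s = _nan_sem(S)
        if input_track is None:
            profile, sem = mean_s, sem_s
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean_i = np.nanmean(np.vstack(input_rows), axis=0)
            profile, sem = mean_s / mean_i, sem_s / mean_i
        out[str(cls)] = pd.DataFrame({
            "offset_bp": offs * w,
            "profile": profile,
            "sem": sem,
            "n": np.isfinite(S).sum(axis=0),
        })
    for cls in pd.unique(genes[class_column]):
        if str(cls) not in out:
            warnings.warn(f"expression class {cls!r} has no eligible genes",
                          stacklevel=2)
    return out


def rt_decile_hist2d(
    chip_track: BinnedTrack,
    rt_smoothed: BinnedTrack,
    select_mask: dict[str, np.ndarray] | None = None,
    restriction_mask: dict[str, np.ndarray] | None = None,
    n_value_bins: int = 50,
    value_cap_quantile: float = 0.995,
) -> dict:
    """Column-normalized 2D histogram of ChIP signal by RT decile.

    Columns are the deciles of the whole-genome timing distribution; within
    each column the ChIP relative-frequency histogram is normalized to a
    probability distribution. The value axis uses ``n_value_bins`` equal
    bins on [0, P99.5 of the genome-wide signal] plus one overflow bin.
    Per-column summary statistics (mean, median, quartiles, first/ninth
    decile, count) are reported for boxplot-style display.
    """
    if not chip_track.congruent(rt_smoothed):
        raise ValueError("chip and RT tracks are not congruent")
    rt_all = rt_smoothed.genome_values()
    rt_all = rt_all[np.isfinite(rt_all)]
    decile_edges = np.quantile(rt_all, np.linspace(0, 1, 11))
    chip_all = chip_track.genome_values()
    chip_all = chip_all[np.isfinite(chip_all)]
    cap = float(np.quantile(chip_all, value_cap_quantile))
    value_edges = np.concatenate(
        [np.linspace(0, cap, n_value_bins + 1), [np.inf]])
    chips, rts = [], []
    for chrom in chip_track.chrom_sizes:
        sel = np.isfinite(chip_track.data[chrom]) & \
            np.isfinite(rt_smoothed.data[chrom])
        if select_mask is not None:
            sel &= select_mask[chrom]
        if restriction_mask is not None:
            sel &= restriction_mask[chrom]
        chips.append(chip_track.data[chrom][sel])
        rts.append(rt_smoothed.data[chrom][sel])
    chip = np.concatenate(chips)
    rt = np.concatenate(rts)
    col = np.clip(np.searchsorted(decile_edges[1:-1], rt, side="right"), 0, 9)
    hist = np.full((n_value_bins + 1, 10), np.nan)
    stats_rows = []
    for c in range(10):
        vals = chip[col == c]
        if len(vals) == 0:
            stats_rows.append({"mean": np.nan, "median": np.nan,
                               "q1": np.nan, "q3": np.nan,
                               "d1": np.nan, "d9": np.nan, "n": 0})
            continue
        h, _ = np.histogram(vals, bins=value_edges)
        hist[:, c] = h / h.sum()
        q = np.quantile(vals, [0.1, 0.25, 0.5, 0.75, 0.9])
        stats_rows.append({"mean": float(vals.mean()), "median": float(q[2]),
                           "q1": float(q[1]), "q3": float(q[3]),
                           "d1": float(q[0]), "d9": float(q[4]),
                           "n": int(len(vals))})
    return {
        "hist": hist,
        "rt_decile_edges": decile_edges,
        "value_edges": value_edges,
        "column_stats": pd.DataFrame(stats_rows),
        "n_bins": int(len(chip)),
    }


def ks_z(sample_a, sample_b) -> KsResult:
    """Two-sample KS distance with the sqrt(nm/(n+m)) size correction."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    d = float(sps.ks_2samp(a, b).statistic)
    n, m = len(a), len(b)
    return KsResult(d=d, z=d * np.sqrt(n * m / (n + m)), n=n, m=m)


def welch_t_one_sided(a, b, alternative: str = "greater") -> tuple[float, float]:
    """One-sided two-sample t test with Welch (Satterthwaite) correction.

    ``alternative='greater'`` tests mean(a) > mean(b). When both groups
    have zero variance and equal means the test is undefined; p = 0.5 is
    returned by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
    stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(stat) and a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 0.0, 0.5
    return stat, p


def anova_tukey(groups: Sequence[np.ndarray]) -> dict:
    """One-way ANOVA omnibus test followed by Tukey HSD pairwise comparisons.

    Returns the F statistic, the omnibus p value, and a matrix of
    family-wise-adjusted pairwise p values (95% family-wise confidence).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    f, p = sps.f_oneway(*groups)
    tk = sps.tukey_hsd(*groups)
    return {"f": float(f), "p": float(p), "tukey_p": np.asarray(tk.pvalue)}
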