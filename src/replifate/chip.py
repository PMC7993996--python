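"""Bin-level ChIP-seq quantification.

The normalization chain is: sum replicate counts per bin (read frequency),
divide by the genome-wide mean (normalized read frequency, mean 1), then
mask bins with zero input reads and divide by the equally normalized input
(relative read frequency). The zero-input mask is shared by every sample of
an analysis run so all factors are compared on the same bin set.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .core import BinnedTrack

__all__ = [
    "combine_replicates",
    "normalize_mean",
    "input_normalize",
    "zero_input_mask",
    "track_correlation_matrix",
]


def combine_replicates(tracks: list[BinnedTrack]) -> BinnedTrack:
    """Element-wise sum of replicate count tracks (missing counts as 0)."""
    if not tracks:
        raise ValueError("no tracks given")
    first = tracks[0]
    for t in tracks[1:]:
        if not first.congruent(t):
            raise ValueError("tracks have mismatched bin geometry")
    out = BinnedTrack.like(first)
    for chrom in out.chrom_sizes:
        out.data[chrom] = np.sum(
            [np.nan_to_num(t.data[chrom], nan=0.0) for t in tracks], axis=0)
    return out


def normalize_mean(counts: BinnedTrack) -> BinnedTrack:
    """Divide every bin by the genome-wide mean over full, non-missing bins.

    The output has mean exactly 1 over those bins, making tracks of
    different sequencing depth comparable.
    """
    mean = counts.genome_mean()
    if not np.isfinite(mean) or mean == 0:
        raise ValueError("cannot normalize an all-zero or all-missing track")
    out = counts.copy()
    for chrom in out.chrom_sizes:
        out.data[chrom] = out.data[chrom] / mean
    return out


def zero_input_mask(input_counts: BinnedTrack) -> dict[str, np.ndarray]:
    """Boolean per-chromosome mask of bins with no reads in the input."""
    return {
        chrom: ~(np.nan_to_num(v, nan=0.0) > 0)
        for chrom, v in input_counts.data.items()
    }


def input_normalize(
    sample_norm: BinnedTrack,
    input_norm: BinnedTrack,
    mask: dict[str, np.ndarray] | None = None,
) -> BinnedTrack:
    """Relative read frequency: sample / input on mean-normalized tracks.

    Bins in ``mask`` (zero input reads, computed from the raw input when not
    supplied) become missing. The same mask should be applied to every
    sample of a run.
    """
    if not sample_norm.congruent(input_norm):
        raise ValueError("sample and input tracks are not congruent")
    if mask is None:
        mask = zero_input_mask(input_norm)
    out = BinnedTrack.like(sample_norm)
    for chrom in out.chrom_sizes:
        s = sample_norm.data[chrom]
        i = input_norm.data[chrom]
        with np.errstate(invalid="ignore", divide="ignore"):
            v = s / i
        v[mask[chrom]] = np.nan
        v[~np.isfinite(v)] = np.nan
        out.data[chrom] = v
    return out


def track_correlation_matrix(
    tracks: dict[str, BinnedTrack], method: str = "pearson"
) -> tuple[np.ndarray, list[str]]:
    """Pairwise track correlation with complete-linkage clustering order.

    Correlations use pairwise-complete bins; the dendrogram is built on the
    correlation distance d = 1 − r with complete linkage. Returns the
    correlation matrix (in input order) and the clustered leaf name order.
    """
    if method != "pearson":
        raise ValueError("only pearson correlation is supported")
    names = list(tracks)
    if len(names) < 2:
        raise ValueError("need at least 2 tracks")
    mats = [tracks[n].genome_values() for n in names]
    k = len(names)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            ok = np.isfinite(mats[i]) & np.isfinite(mats[j])
            if ok.sum() < 2:
                warnings.warn(
                    f"fewer than 2 shared bins for {names[i]} vs {names[j]}",
                    stacklevel=2)
                r[i, j] = r[j, i] = np.nan
            else:
                r[i, j] = r[j, i] = np.corrcoef(mats[i][ok], mats[j][ok])[0, 1]
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        # drop rows with undefined distances from the clustering only
        keep = ~np.isnan(d).any(axis=1)
        order_idx = np.flatnonzero(keep)
        if keep.sum() >= 2:
            z = linkage(squareform(d[np.ix_(order_idx, order_idx)],
                                   checks=False), method="complete")
            order = [names[order_idx[i]] for i in leaves_list(z)]
        else:
            order = [names[i] for i in order_idx]
        order += [n for i, n in enumerate(names) if not keep[i]]
    else:
        z = linkage(squareform(d, checks=False), method="complete")
        order = [names[i] for i in leaves_list(z)]
    return r, order
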