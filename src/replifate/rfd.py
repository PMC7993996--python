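"""Replication fork directionality (RFD) from stranded Okazaki-fragment counts.

RFD per bin is ``(R − F) / (R + F)`` where ``R`` and ``F`` are reads mapped
to the reverse and forward strand. Okazaki fragments of a rightward-moving
fork map to the reverse strand, so RFD = +1 means purely rightward fork
progression and −1 purely leftward. Upshifts of RFD along a chromosome mark
preferential initiation, downshifts preferential termination.
"""

from __future__ import annotations

import numpy as np

from .core import BinnedTrack, StrandedBinCounts

__all__ = ["pool_replicates", "compute_rfd", "rebin_counts",
           "replicate_rfd_correlation"]


def rebin_counts(counts: StrandedBinCounts, new_width: int) -> StrandedBinCounts:
    """Aggregate stranded counts into coarser bins (sums per new bin)."""
    if new_width % counts.bin_width != 0:
        raise ValueError("new_width must be a multiple of the bin width")
    k = new_width // counts.bin_width
    out = StrandedBinCounts(new_width, dict(counts.chrom_sizes))
    for chrom in counts.chrom_sizes:
        for src, dst in ((counts.R, out.R), (counts.F, out.F)):
            v = src[chrom]
            n_out = len(dst[chrom])
            pad = n_out * k - len(v)
            if pad:
                v = np.concatenate([v, np.zeros(pad, dtype=v.dtype)])
            dst[chrom] = v.reshape(n_out, k).sum(axis=1)
    return out


def pool_replicates(replicates: list[StrandedBinCounts]) -> StrandedBinCounts:
    """Sum R and F element-wise across replicate experiments."""
    if not replicates:
        raise ValueError("no replicates given")
    first = replicates[0]
    for rep in replicates[1:]:
        if not first.congruent(rep):
            raise ValueError("replicates have mismatched bin geometry")
    pooled = StrandedBinCounts(first.bin_width, dict(first.chrom_sizes))
    for chrom in pooled.chrom_sizes:
        pooled.R[chrom] = np.sum([r.R[chrom] for r in replicates], axis=0)
        pooled.F[chrom] = np.sum([r.F[chrom] for r in replicates], axis=0)
    return pooled


def compute_rfd(counts: StrandedBinCounts, min_total: int = 1) -> BinnedTrack:
    """Per-bin RFD = (R − F)/(R + F); bins with R + F < min_total are missing."""
    track = BinnedTrack.like(counts)
    for chrom in counts.chrom_sizes:
        R = counts.R[chrom].astype(float)
        F = counts.F[chrom].astype(float)
        tot = R + F
        with np.errstate(invalid="ignore", divide="ignore"):
            v = (R - F) / tot
        v[tot < max(min_total, 1)] = np.nan
        track.data[chrom] = v
    return track


def _window_sums(counts: StrandedBinCounts, window: int):
    """Sum R and F in non-overlapping windows of ``window`` bp per chromosome."""
    if window % counts.bin_width != 0:
        raise ValueError("window must be a multiple of bin_width")
    k = window // counts.bin_width
    out = {}
    for chrom in counts.chrom_sizes:
        R, F = counts.R[chrom], counts.F[chrom]
        n = (len(R) // k) * k
        out[chrom] = (
            R[:n].reshape(-1, k).sum(axis=1),
            F[:n].reshape(-1, k).sum(axis=1),
        )
    return out


def replicate_rfd_correlation(
    a: StrandedBinCounts,
    b: StrandedBinCounts,
    window: int = 50_000,
    min_reads: int = 101,
) -> float:
    """Pearson correlation of window-level RFD between two replicates.

    RFD is recomputed from window-summed counts (ratio of sums, not mean of
    bin RFDs) in non-overlapping ``window``-bp windows; only windows where
    both replicates have at least ``min_reads`` total reads qualify.
    """
    if not a.congruent(b):
        raise ValueError("replicates have mismatched bin geometry")
    xs, ys = [], []
    wa, wb = _window_sums(a, window), _window_sums(b, window)
    for chrom in a.chrom_sizes:
        Ra, Fa = wa[chrom]
        Rb, Fb = wb[chrom]
        ta, tb = Ra + Fa, Rb + Fb
        ok = (ta >= min_reads) & (tb >= min_reads)
        if ok.any():
            xs.append((Ra[ok] - Fa[ok]) / ta[ok])
            ys.append((Rb[ok] - Fb[ok]) / tb[ok])
    if not xs or sum(len(x) for x in xs) < 2:
        raise ValueError("fewer than 2 qualifying windows")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    return float(np.corrcoef(x, y)[0, 1])
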