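"""Classification of replication segments by transcription and chromatin.

Ascending segments (initiation zones) are typed by their transcriptional
context: type 1 has an actively transcribed gene within 20 kb of both
borders, type 2 of exactly one border (oriented so the transcribed side is
the right border), non-genic ASs have no annotated gene within 20 kb at
all, and the genic remainder is kept as an explicit fourth label so the
accounting stays auditable.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import BinnedTrack, Segment, empty_intervals, merge_intervals

__all__ = [
    "classify_as",
    "subset_by_mark",
    "intersect_replicate_peaks",
    "region_mean_frequency",
    "genes_exclusion_zone",
    "interval_bin_mask",
    "segments_to_intervals",
]


def segments_to_intervals(segments: Iterable[Segment]) -> pd.DataFrame:
    rows = [(s.chrom, s.pos_5p, s.pos_3p) for s in segments]
    if not rows:
        return empty_intervals()
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).astype(
        {"start": np.int64, "end": np.int64})


def classify_as(
    as_list: Sequence[Segment],
    genes: pd.DataFrame,
    tpm_threshold: float = 3.0,
    flank: int = 20_000,
) -> list[Segment]:
    """Annotate ascending segments with their transcriptional AS type.

    An AS extended by ``flank`` on both sides that overlaps no annotated
    gene is non-genic. Among genic ASs, a border "qualifies" when at least
    one transcribed gene (TPM > ``tpm_threshold``) body lies within
    ``flank`` of the border on the outward side (or overlapping it): both
    borders → type1, exactly one → type2 with ``orientation_flipped`` set so
    the transcribed side is the right border, neither → genic_other.
    """
    out: list[Segment] = []
    for seg in as_list:
        g = genes[genes["chrom"] == seg.chrom]
        gs = g["start"].to_numpy()
        ge = g["end"].to_numpy()
        tpm = g["tpm"].to_numpy(dtype=float)
        any_overlap = (ge > seg.pos_5p - flank) & (gs < seg.pos_3p + flank)
        if not any_overlap.any():
            out.append(dataclasses.replace(seg, as_type="non_genic",
                                           orientation_flipped=False))
            continue
        expressed = tpm > tpm_threshold
        left = expressed & (ge > seg.pos_5p - flank) & (gs <= seg.pos_5p)
        right = expressed & (gs < seg.pos_3p + flank) & (ge >= seg.pos_3p)
        if left.any() and right.any():
            as_type, flipped = "type1", False
        elif left.any() or right.any():
            as_type, flipped = "type2", bool(left.any())
        else:
            as_type, flipped = "genic_other", False
        out.append(dataclasses.replace(seg, as_type=as_type,
                                       orientation_flipped=flipped))
    return out


def _interval_mean(track: BinnedTrack, chrom: str, start: int, end: int) -> float:
    w = track.bin_width
    b0 = start // w
    b1 = -(-end // w)
    v = track.data[chrom][b0:b1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(np.nanmean(v)) if len(v) else np.nan


def subset_by_mark(
    intervals: Sequence[Segment],
    mark_track: BinnedTrack,
    sd_multiple: float = 1.5,
) -> tuple[list[Segment], list[Segment], list[Segment]]:
    """Split intervals into mark-high / mark-low / neither sets.

    Each interval's mean relative read frequency ``m`` is compared with the
    genome-wide mean ``mu`` and SD ``s`` of the mark track: high when
    ``m > mu + sd_multiple*s``, low when ``m < mu``, neither otherwise. The
    three sets partition the input.
    """
    v = mark_track.genome_values()
    mu = float(np.nanmean(v))
    s = float(np.nanstd(v))
    high: list[Segment] = []
    low: list[Segment] = []
    neither: list[Segment] = []
    for seg in intervals:
        m = _interval_mean(mark_track, seg.chrom, seg.pos_5p, seg.pos_3p)
        if np.isnan(m):
            warnings.warn(
                f"interval {seg.chrom}:{seg.pos_5p}-{seg.pos_3p} has no "
                "covered bins; assigned to 'neither'", stacklevel=2)
            neither.append(seg)
        elif m > mu + sd_multiple * s:
            high.append(seg)
        elif m < mu:
            low.append(seg)
        else:
            neither.append(seg)
    return high, low, neither


def intersect_replicate_peaks(peak_sets: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Peaks of the first set reproduced (>= 1 bp overlap) in every other set.

    Returns the union-merge of the retained first-set peaks; any empty
    input set empties the output.
    """
    if len(peak_sets) < 2:
        raise ValueError("need at least 2 peak sets")
    if any(len(p) == 0 for p in peak_sets):
        return empty_intervals()
    first = peak_sets[0]
    keep = np.ones(len(first), dtype=bool)
    for other in peak_sets[1:]:
        for idx, (chrom, s, e) in enumerate(
                zip(first["chrom"], first["start"], first["end"])):
            if not keep[idx]:
                continue
            o = other[other["chrom"] == chrom]
            if not ((o["end"].to_numpy() > s) & (o["start"].to_numpy() < e)).any():
                keep[idx] = False
    return merge_intervals(first[keep])


def genes_exclusion_zone(genes: pd.DataFrame, pad: int = 10_000) -> pd.DataFrame:
    """Merged gene bodies extended by ``pad`` on both sides."""
    if len(genes) == 0:
        return empty_intervals()
    iv = genes[["chrom", "start", "end"]].copy()
    iv["start"] = np.maximum(iv["start"] - pad, 0)
    iv["end"] = iv["end"] + pad
    return merge_intervals(iv)


def interval_bin_mask(
    track: BinnedTrack, intervals: pd.DataFrame, fully_inside: bool = True
) -> dict[str, np.ndarray]:
    """Per-chromosome boolean mask of bins inside (or overlapping) intervals."""
    mask = {c: np.zeros(track.n_bins(c), dtype=bool) for c in track.chrom_sizes}
    w = track.bin_width
    for chrom, grp in intervals.groupby("chrom"):
        if chrom not in mask:
            continue
        m = mask[chrom]
        n = len(m)
        for s, e in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
            if fully_inside:
                b0, b1 = -(-s // w), e // w       # bins fully covered
            else:
                b0, b1 = s // w, -(-e // w)       # bins overlapping
            m[max(0, b0):min(n, b1)] = True
    return mask


def region_mean_frequency(
    classes: dict[str, pd.DataFrame],
    track: BinnedTrack,
    exclusion: pd.DataFrame | None = None,
    ratio_between: tuple[str, str] | None = None,
    fully_inside: bool = True,
) -> dict:
    """Mean relative read frequency (± 2 SEM) of binned signal per region class.

    Bins overlapping the ``exclusion`` intervals (typically genes ± 10 kb)
    are dropped first. Returns per class mean, SEM, and bin count, plus the
    ratio of means between two named classes when requested.
    """
    excl = (interval_bin_mask(track, exclusion, fully_inside=False)
            if exclusion is not None and len(exclusion) else None)
    rows = {}
    for name, intervals in classes.items():
        vals = []
        in_class = interval_bin_mask(track, intervals, fully_inside=fully_inside)
        for chrom in track.chrom_sizes:
            sel = in_class[chrom].copy()
            if excl is not None:
                sel &= ~excl[chrom]
            v = track.data[chrom][sel]
            vals.append(v[np.isfinite(v)])
        v = np.concatenate(vals) if vals else np.array([])
        if len(v) == 0:
            raise ValueError(f"region class {name!r} has no qualifying bins")
        rows[name] = {
            "mean": float(v.mean()),
            "sem": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
            "n": int(len(v)),
        }
    result = {"classes": pd.DataFrame(rows).T}
    if ratio_between is not None:
        a, b = ratio_between
        result["ratio"] = rows[a]["mean"] / rows[b]["mean"]
    return result
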