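"""Interval-shuffling null model and RFD aggregation around interval sets.

Used to test whether an interval set (e.g. predicted early-replication
control elements) sits on replication initiation signal: the observed
aggregate RFD profile around interval centers is compared with profiles
around intervals re-placed uniformly at random on the same chromosome,
keeping per-chromosome counts and lengths and avoiding assembly gaps.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .core import BinnedTrack, empty_intervals

__all__ = ["shuffle_intervals", "aggregate_rfd_at"]


def _mask_arrays(gap_mask: pd.DataFrame | None):
    if gap_mask is None or len(gap_mask) == 0:
        return {}
    return {
        chrom: (grp["start"].to_numpy(), grp["end"].to_numpy())
        for chrom, grp in gap_mask.sort_values("start").groupby("chrom")
    }


def _admissible_starts(size: int, length: int,
                       mask: tuple[np.ndarray, np.ndarray] | None):
    """Maximal runs of admissible start positions as (starts, ends, cum)."""
    if length > size:
        raise ValueError("interval longer than its chromosome")
    if mask is None:
        seg_s = np.array([0], dtype=np.int64)
        seg_e = np.array([size - length + 1], dtype=np.int64)
    else:
        gs, ge = mask
        free_s, free_e = [], []
        prev = 0
        for s, e in zip(gs, ge):
            if s > prev:
                free_s.append(prev)
                free_e.append(s)
            prev = max(prev, e)
        if prev < size:
            free_s.append(prev)
            free_e.append(size)
        seg_s, seg_e = [], []
        for s, e in zip(free_s, free_e):
            if e - s >= length:
                seg_s.append(s)
                seg_e.append(e - length + 1)  # exclusive end of valid starts
        seg_s = np.array(seg_s, dtype=np.int64)
        seg_e = np.array(seg_e, dtype=np.int64)
    cum = np.concatenate(([0], np.cumsum(seg_e - seg_s)))
    return seg_s, seg_e, cum


def shuffle_intervals(
    intervals: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    gap_mask: pd.DataFrame | None = None,
    seed: int | np.random.Generator = 0,
    n_draws: int = 1,
    allow_self_overlap: bool = True,
    max_retries: int = 10_000,
) -> list[pd.DataFrame]:
    """Uniformly re-place each interval on its chromosome, avoiding gaps.

    Lengths and per-chromosome counts are preserved exactly. Starts are
    drawn uniformly from the exact admissible set (positions where the
    placed interval overlaps no gap-mask region and stays on the
    chromosome), so a single admissible slot is always found. With
    ``allow_self_overlap=False`` placements colliding with earlier
    intervals of the same draw are rejected and redrawn (up to
    ``max_retries`` per interval, then the whole draw restarts).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    masks = _mask_arrays(gap_mask)
    adm_cache: dict[tuple[str, int], tuple] = {}

    def admissible(chrom: str, length: int):
        key = (chrom, length)
        if key not in adm_cache:
            try:
                adm = _admissible_starts(chrom_sizes[chrom], length,
                                         masks.get(chrom))
            except ValueError as exc:
                raise ValueError(f"{chrom}: {exc}") from None
            adm_cache[key] = adm
        return adm_cache[key]

    items = list(zip(intervals["chrom"], intervals["start"],
                     intervals["end"]))
    draws: list[pd.DataFrame] = []
    for _ in range(n_draws):
        for _restart in range(100):
            rows = []
            placed: dict[str, list[tuple[int, int]]] = {}
            ok = True
            for chrom, s, e in items:
                length = int(e) - int(s)
                seg_s, seg_e, cum = admissible(chrom, length)
                if cum[-1] == 0:
                    raise RuntimeError(
                        f"no admissible placement for {chrom}:{s}-{e}; "
                        "mask too dense")
                for _attempt in range(max_retries):
                    u = int(rng.integers(0, cum[-1]))
                    k = int(np.searchsorted(cum, u, side="right") - 1)
                    start = int(seg_s[k] + (u - cum[k]))
                    stop = start + length
                    if not allow_self_overlap and any(
                            pe > start and ps < stop
                            for ps, pe in placed.get(chrom, [])):
                        continue
                    break
                else:
                    ok = False
                    break
                rows.append((chrom, start, stop))
                placed.setdefault(chrom, []).append((start, stop))
            if ok:
                break
        else:
            raise RuntimeError(
                f"could not place all intervals without self-overlap after "
                f"{max_retries} retries x 100 draw restarts")
        draws.append(
            pd.DataFrame(rows, columns=["chrom", "start", "end"]).astype(
                {"start": np.int64, "end": np.int64})
            if rows else empty_intervals())
    return draws


def aggregate_rfd_at(
    intervals: pd.DataFrame,
    rfd: BinnedTrack,
    halfwidth: int = 500_000,
    band: str = "se",
) -> pd.DataFrame:
    """Mean RFD profile around interval centers with a 95% envelope.

    Profiles are aligned on interval centers with the track's binning step;
    per position the mean across intervals and the envelope
    ``mean ± 1.96·SD/sqrt(n)`` (``band='se'``, default) or
    ``mean ± 1.96·SD`` (``band='sd'``) are reported, together with the
    number of contributing intervals (positions beyond chromosome ends
    lose intervals).
    """
    if len(intervals) == 0:
        raise ValueError("empty interval set")
    if band not in ("se", "sd"):
        raise ValueError("band must be 'se' or 'sd'")
    w = rfd.bin_width
    offs = np.arange(-(halfwidth // w), halfwidth // w + 1)
    rows = []
    for chrom, s, e in zip(intervals["chrom"], intervals["start"],
                           intervals["end"]):
        center_bin = ((int(s) + int(e)) // 2) // w
        v = rfd.data[chrom]
        idx = center_bin + offs
        row = np.full(len(offs), np.nan)
        ok = (idx >= 0) & (idx < len(v))
        row[ok] = v[idx[ok]]
        rows.append(row)
    mat = np.vstack(rows)
    n = np.isfinite(mat).sum(axis=0)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    sd = np.where(n > 1, sd, 0.0)
    half = 1.96 * (sd / np.sqrt(np.maximum(n, 1)) if band == "se" else sd)
    return pd.DataFrame({
        "offset_bp": offs * w,
        "mean": mean,
        "lo": mean - half,
        "hi": mean + half,
        "n": n,
    })
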