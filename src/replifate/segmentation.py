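"""Segmentation of replication-program tracks.

Initiation zones appear as ascending segments (AS) and termination zones as
descending segments (DS) of the RFD profile. Both are delineated from the
convexity of the Gaussian-smoothed profile: convolving RFD with the second
derivative of a Gaussian (sigma = 32 kb by default) turns each quasi-linear
upshift into a positive convexity extremum at its foot and a negative one at
its shoulder; segments span consecutive opposite-sign extrema of large
amplitude.

Constant-RFD region calling (unidirectionally replicating regions, URR, and
null-RFD regions, NRR) and replication-timing domain (RTD) calling from
smoothed log2(Early/Late) tracks live here as well.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import BinnedTrack, Segment

__all__ = [
    "ConvexitySettings",
    "smooth_convexity",
    "detect_segments",
    "filter_segments",
    "detect_constant_rfd",
    "smooth_rt",
    "detect_rtds",
]

CONSTANT_RFD_DEFAULTS = {
    # mode: (|RFD| threshold, minimum run length in bp)
    "URR": (0.8, 300_000),
    "NRR": (0.15, 500_000),
}


@dataclass
class ConvexitySettings:
    """Parameters of the convexity transform and extremum selection.

    ``sigma`` is the Gaussian standard deviation in bp. The amplitude
    threshold for extrema is either an absolute convexity value or, by
    default, a multiple of the robust (MAD-based) SD of the genome-wide
    convexity track — a scale-free stand-in for a conservatively hand-set
    cutoff.
    """

    sigma: float = 32_000.0
    truncation_sigmas: float = 4.0
    amplitude_threshold_mode: str = "robust_sd_multiple"
    threshold_value: float = 2.0
    max_gap_bins: int = 10  # linear interpolation limit for missing runs

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.truncation_sigmas < 3:
            raise ValueError("kernel truncation must be at least 3 sigma")
        if self.amplitude_threshold_mode not in ("absolute", "robust_sd_multiple"):
            raise ValueError("unknown amplitude_threshold_mode")


def gaussian_second_derivative_kernel(sigma: float, bin_width: int,
                                      truncation_sigmas: float = 4.0) -> np.ndarray:
    """Discrete g''(x) = (x^2 − s^2)/s^4 · N(x; 0, s), zero-sum enforced."""
    half = int(math.ceil(truncation_sigmas * sigma / bin_width))
    x = np.arange(-half, half + 1) * float(bin_width)
    g = np.exp(-x * x / (2 * sigma * sigma)) / (sigma * math.sqrt(2 * math.pi))
    k = (x * x - sigma * sigma) / sigma**4 * g * bin_width
    return k - k.mean()


def _interpolate_short_gaps(v: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly fill missing runs of length <= max_gap bounded by data."""
    out = v.copy()
    isnan = np.isnan(v)
    if not isnan.any():
        return out
    d = np.diff(np.concatenate(([0], isnan.view(np.int8), [0])))
    for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
        if e - s <= max_gap and s > 0 and e < len(v):
            out[s:e] = np.interp(np.arange(s, e), [s - 1, e], [v[s - 1], v[e]])
    return out


def _finite_runs(v: np.ndarray):
    ok = np.isfinite(v)
    d = np.diff(np.concatenate(([0], ok.view(np.int8), [0])))
    return zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1))


def smooth_convexity(rfd: BinnedTrack, settings: ConvexitySettings | None = None
                     ) -> BinnedTrack:
    """Convexity of the Gaussian-smoothed RFD profile.

    Missing runs up to ``max_gap_bins`` are bridged by linear interpolation;
    longer gaps split the chromosome into independent detection domains.
    Output is missing wherever the kernel does not fully overlap data, so
    extrema are never fabricated from domain edges.
    """
    settings = settings or ConvexitySettings()
    if rfd.bin_width > settings.sigma / 8:
        raise ValueError("bin_width must be <= sigma/8 for a stable transform")
    kernel = gaussian_second_derivative_kernel(
        settings.sigma, rfd.bin_width, settings.truncation_sigmas)
    half = len(kernel) // 2
    out = BinnedTrack.like(rfd)
    for chrom in rfd.chrom_sizes:
        v = _interpolate_short_gaps(rfd.data[chrom], settings.max_gap_bins)
        res = out.data[chrom]
        any_domain = False
        for s, e in _finite_runs(v):
            if e - s < len(kernel):
                continue
            any_domain = True
            res[s + half:e - half] = np.convolve(v[s:e], kernel, mode="valid")
        if not any_domain and len(v):
            warnings.warn(
                f"{chrom}: no data domain longer than the convexity kernel; "
                "output all-missing", stacklevel=2)
    return out


def amplitude_threshold(convexity: BinnedTrack,
                        settings: ConvexitySettings) -> float:
    """Resolve the extremum amplitude threshold for a convexity track."""
    if settings.amplitude_threshold_mode == "absolute":
        return float(settings.threshold_value)
    v = convexity.genome_values()
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return math.inf
    mad = np.median(np.abs(v - np.median(v)))
    return float(settings.threshold_value * 1.4826 * mad)


def _extrema(c: np.ndarray, offset: int, thr: float):
    """Super-threshold local extrema as (bin, sign, amplitude) tuples."""
    ev = []
    pos, _ = find_peaks(c)
    for i in pos:
        if c[i] >= thr:
            ev.append((offset + i, +1, c[i]))
    neg, _ = find_peaks(-c)
    for i in neg:
        if -c[i] >= thr:
            ev.append((offset + i, -1, -c[i]))
    ev.sort()
    return ev


def _collapse_same_sign(events):
    """Among consecutive same-sign extrema keep the largest amplitude."""
    out = []
    for pos, sign, amp in events:
        if out and out[-1][1] == sign:
            if amp > out[-1][2]:
                out[-1] = (pos, sign, amp)
        else:
            out.append((pos, sign, amp))
    return out


def detect_segments(
    convexity: BinnedTrack,
    rfd: BinnedTrack,
    settings: ConvexitySettings | None = None,
) -> tuple[list[Segment], list[Segment]]:
    """Delineate AS and DS segments from convexity extrema.

    Each (positive extremum, next negative extremum) pair bounds one AS;
    (negative, next positive) pairs bound DS. Sub-threshold extrema are
    ignored and runs of same-sign super-threshold extrema collapse to the
    largest. ``delta_rfd`` is RFD(pos_3p) − RFD(pos_5p) with each border RFD
    estimated as the mean over one sigma just outside the segment.
    """
    settings = settings or ConvexitySettings()
    if not convexity.congruent(rfd):
        raise ValueError("convexity and RFD tracks are not congruent")
    thr = amplitude_threshold(convexity, settings)
    w = rfd.bin_width
    flank = max(1, int(round(settings.sigma / w)))
    as_list: list[Segment] = []
    ds_list: list[Segment] = []
    for chrom in convexity.chrom_sizes:
        c = convexity.data[chrom]
        r = rfd.data[chrom]
        for s, e in _finite_runs(c):
            events = _collapse_same_sign(_extrema(c[s:e], s, thr))
            for (p0, s0, _), (p1, s1, _) in zip(events, events[1:]):
                seg = Segment(
                    chrom=chrom,
                    pos_5p=p0 * w,
                    pos_3p=p1 * w,
                    kind="AS" if s0 > 0 else "DS",
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    r5 = np.nanmean(r[max(0, p0 - flank):p0])
                    r3 = np.nanmean(r[p1:p1 + flank])
                seg.delta_rfd = float(r3 - r5)
                (as_list if s0 > 0 else ds_list).append(seg)
    return as_list, ds_list


def filter_segments(
    segments: list[Segment],
    min_length: int = 20_000,
    min_delta: float = 0.5,
    use_abs: bool = False,
) -> list[Segment]:
    """Keep segments with length > min_length and ΔRFD > min_delta (strict).

    With ``use_abs`` the magnitude of ΔRFD is compared instead, which is the
    symmetric rule for descending segments (ΔRFD < −min_delta).
    """
    def delta(s: Segment) -> float:
        return abs(s.delta_rfd) if use_abs else s.delta_rfd

    return [s for s in segments
            if s.length > min_length and delta(s) > min_delta]


def detect_constant_rfd(
    rfd: BinnedTrack,
    mode: str,
    threshold: float | None = None,
    min_length: int | None = None,
) -> list[Segment]:
    """Maximal constant-RFD runs: URR (|RFD| > thr) or NRR (|RFD| < thr).

    Every bin of a run must satisfy the condition; missing bins break runs;
    a run qualifies when it spans at least ``min_length`` bp (300 kb for
    URRs, 500 kb for NRRs by default).
    """
    if mode not in CONSTANT_RFD_DEFAULTS:
        raise ValueError("mode must be 'URR' or 'NRR'")
    d_thr, d_len = CONSTANT_RFD_DEFAULTS[mode]
    thr = d_thr if threshold is None else threshold
    min_len = d_len if min_length is None else min_length
    out: list[Segment] = []
    w = rfd.bin_width
    for chrom in rfd.chrom_sizes:
        v = rfd.data[chrom]
        ok = np.isfinite(v) & (np.abs(v) > thr if mode == "URR"
                               else np.abs(v) < thr)
        d = np.diff(np.concatenate(([0], ok.view(np.int8), [0])))
        for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
            end = min(e * w, rfd.chrom_sizes[chrom])
            if end - s * w >= min_len:
                out.append(Segment(chrom, s * w, end, kind=mode))
    return out


def smooth_rt(rt_10kb: BinnedTrack, window: int = 100_000) -> BinnedTrack:
    """Replication timing smoothed over a centered 100-kb window.

    With 10-kb bins the window is 10 bins; the unavoidable asymmetry of an
    even window is resolved to the lower side: bin ``i`` averages bins
    ``i−5 … i+4`` (non-missing only; truncated at chromosome ends).
    """
    k = window // rt_10kb.bin_width
    lo_off, hi_off = -(k // 2), k - k // 2  # i-5 .. i+4 for k = 10
    out = BinnedTrack.like(rt_10kb)
    for chrom in rt_10kb.chrom_sizes:
        v = rt_10kb.data[chrom]
        n = len(v)
        finite = np.isfinite(v)
        x0 = np.where(finite, v, 0.0)
        S = np.concatenate(([0.0], np.cumsum(x0)))
        C = np.concatenate(([0], np.cumsum(finite.astype(np.int64))))
        i = np.arange(n)
        lo = np.clip(i + lo_off, 0, n)
        hi = np.clip(i + hi_off, 0, n)
        counts = C[hi] - C[lo]
        with np.errstate(invalid="ignore"):
            out.data[chrom] = np.where(
                counts > 0, (S[hi] - S[lo]) / np.maximum(counts, 1), np.nan)
    return out


def detect_rtds(
    rt_smoothed: BinnedTrack,
    early_thr: float = 1.6,
    late_thr: float = -2.0,
    merge_gap: int = 0,
) -> tuple[list[Segment], list[Segment]]:
    """Early / late replication-timing domains from a smoothed RT track.

    Early RTDs are maximal runs with log2(E/L) > early_thr, late RTDs runs
    with log2(E/L) < late_thr (strict inequalities; missing bins break
    runs). ``merge_gap`` optionally merges domains separated by at most
    that many bp; it is off by default.
    """
    def call(cond_fn, kind: str) -> list[Segment]:
        segs: list[Segment] = []
        w = rt_smoothed.bin_width
        for chrom in rt_smoothed.chrom_sizes:
            v = rt_smoothed.data[chrom]
            ok = np.isfinite(v) & cond_fn(v)
            d = np.diff(np.concatenate(([0], ok.view(np.int8), [0])))
            runs = list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))
            if merge_gap > 0 and runs:
                merged = [list(runs[0])]
                for s, e in runs[1:]:
                    if (s - merged[-1][1]) * w <= merge_gap:
                        merged[-1][1] = e
                    else:
                        merged.append([s, e])
                runs = [tuple(r) for r in merged]
            for s, e in runs:
                end = min(e * w, rt_smoothed.chrom_sizes[chrom])
                segs.append(Segment(chrom, s * w, end, kind=kind))
        return segs

    early = call(lambda v: v > early_thr, "RTD_early")
    late = call(lambda v: v < late_thr, "RTD_late")
    return early, late
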