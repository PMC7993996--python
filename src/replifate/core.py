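"""Domain containers and on-disk formats for replication-program analysis.

Conventions used throughout the package:

* coordinates are 0-based, half-open, as in BED/bedGraph;
* a genome is binned into fixed-width, non-overlapping bins; bin ``i`` of a
  chromosome covers ``[i*w, (i+1)*w)`` and the final partial bin (when the
  chromosome length is not a multiple of ``w``) is kept but flagged so that
  genome-wide summary statistics can exclude it;
* missing data is ``NaN``, never silently zero, and propagates through
  arithmetic;
* text output uses 6 significant digits so write/read round-trips are exact
  at the declared precision.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BinnedTrack",
    "StrandedBinCounts",
    "Segment",
    "KsResult",
    "GENE_COLUMNS",
    "read_bedgraph",
    "write_bedgraph",
    "write_segments_bed",
    "read_segments_bed",
    "read_intervals_bed",
    "write_intervals_bed",
    "read_gene_table",
    "write_gene_table",
    "read_rt_table",
    "n_gap_mask",
    "merge_intervals",
    "empty_intervals",
]

FMT = "%.6g"  # text precision for all numeric track output

#: column contract for gene tables (TSV on disk, DataFrame in memory)
GENE_COLUMNS = [
    "gene_id",
    "chrom",
    "start",
    "end",
    "strand",
    "exonic_length_kb",
    "read_count",
    "tpm",
    "activity_class",
]


def _n_bins(size: int, width: int) -> int:
    return -(-size // width)


@dataclass
class BinnedTrack:
    """Fixed-width binned numeric signal over a set of chromosomes.

    ``data`` maps chromosome name to a float vector of length
    ``ceil(chrom_size / bin_width)``; ``NaN`` marks missing bins.
    """

    bin_width: int
    chrom_sizes: dict[str, int]
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for chrom, size in self.chrom_sizes.items():
            n = _n_bins(size, self.bin_width)
            if chrom not in self.data:
                self.data[chrom] = np.full(n, np.nan)
            elif len(self.data[chrom]) != n:
                raise ValueError(
                    f"{chrom}: expected {n} bins for size {size} at "
                    f"bin_width {self.bin_width}, got {len(self.data[chrom])}"
                )
            self.data[chrom] = np.asarray(self.data[chrom], dtype=float)

    # -- geometry -----------------------------------------------------------
    def n_bins(self, chrom: str) -> int:
        return _n_bins(self.chrom_sizes[chrom], self.bin_width)

    def bin_index(self, chrom: str, pos: int) -> int:
        if pos < 0 or pos >= self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return pos // self.bin_width

    def bin_start(self, chrom: str, i: int) -> int:
        if i < 0 or i >= self.n_bins(chrom):
            raise ValueError(f"bin {i} outside {chrom}")
        return i * self.bin_width

    def has_partial_last_bin(self, chrom: str) -> bool:
        return self.chrom_sizes[chrom] % self.bin_width != 0

    def full_bin_slice(self, chrom: str) -> slice:
        """Slice selecting only bins fully inside the chromosome."""
        n = self.n_bins(chrom)
        return slice(0, n - 1 if self.has_partial_last_bin(chrom) else n)

    # -- whole-genome views -------------------------------------------------
    def genome_values(self, include_partial: bool = False) -> np.ndarray:
        parts = []
        for chrom in self.chrom_sizes:
            v = self.data[chrom]
            parts.append(v if include_partial else v[self.full_bin_slice(chrom)])
        return np.concatenate(parts) if parts else np.array([])

    def genome_mean(self) -> float:
        """Mean over non-missing full bins (partial edge bins excluded)."""
        v = self.genome_values()
        return float(np.nanmean(v))

    def congruent(self, other: "BinnedTrack | StrandedBinCounts") -> bool:
        return (
            self.bin_width == other.bin_width
            and self.chrom_sizes == other.chrom_sizes
        )

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            self.bin_width,
            dict(self.chrom_sizes),
            {c: v.copy() for c, v in self.data.items()},
        )

    @classmethod
    def like(cls, other: "BinnedTrack | StrandedBinCounts",
             fill: float = np.nan) -> "BinnedTrack":
        t = cls(other.bin_width, dict(other.chrom_sizes))
        for c in t.data:
            t.data[c][:] = fill
        return t


@dataclass
class StrandedBinCounts:
    """Per-bin Okazaki-fragment read counts split by mapping strand.

    ``R``/``F`` hold non-negative integer counts of reads mapped to the
    reverse / forward strand, on the same bin grid as :class:`BinnedTrack`.
    """

    bin_width: int
    chrom_sizes: dict[str, int]
    R: dict[str, np.ndarray] = field(default_factory=dict)
    F: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            n = _n_bins(size, self.bin_width)
            for attr in ("R", "F"):
                d = getattr(self, attr)
                if chrom not in d:
                    d[chrom] = np.zeros(n, dtype=np.int64)
                else:
                    a = np.asarray(d[chrom], dtype=np.int64)
                    if len(a) != n:
                        raise ValueError(f"{chrom}: {attr} has wrong length")
                    if (a < 0).any():
                        raise ValueError(f"{chrom}: negative {attr} counts")
                    d[chrom] = a

    def congruent(self, other) -> bool:
        return (
            self.bin_width == other.bin_width
            and self.chrom_sizes == other.chrom_sizes
        )


SEGMENT_KINDS = ("AS", "DS", "URR", "NRR", "RTD_early", "RTD_late")
AS_TYPES = ("type1", "type2", "non_genic", "genic_other")


@dataclass
class Segment:
    """A delineated replication-program interval.

    ``delta_rfd`` is the RFD shift across the segment,
    ``RFD(pos_3p) − RFD(pos_5p)``; for ascending segments it measures
    initiation efficiency and lies in [−2, 2].
    """

    chrom: str
    pos_5p: int
    pos_3p: int
    kind: str
    delta_rfd: float = math.nan
    as_type: str | None = None
    orientation_flipped: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.pos_5p < self.pos_3p:
            raise ValueError(f"bad segment coordinates {self.pos_5p}..{self.pos_3p}")
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.as_type is not None and self.as_type not in AS_TYPES:
            raise ValueError(f"unknown AS type {self.as_type!r}")

    @property
    def length(self) -> int:
        return self.pos_3p - self.pos_5p

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.pos_5p + self.pos_3p)


@dataclass(frozen=True)
class KsResult:
    """Two-sample Kolmogorov–Smirnov statistic with sample-size correction.

    ``z`` rescales the ECDF sup-distance ``d`` by ``sqrt(n*m/(n+m))`` so that
    values from differently sized comparisons are on a common scale.
    """

    d: float
    z: float
    n: int
    m: int


# ---------------------------------------------------------------------------
# interval helpers (plain-numpy bed-like DataFrames: chrom, start, end)
# ---------------------------------------------------------------------------

def empty_intervals() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=str),
                         "start": pd.Series(dtype=np.int64),
                         "end": pd.Series(dtype=np.int64)})


def merge_intervals(iv: pd.DataFrame) -> pd.DataFrame:
    """Union-merge possibly overlapping intervals (book-ended ones merge)."""
    if len(iv) == 0:
        return empty_intervals()
    out = []
    for chrom, grp in iv.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"]).astype(
        {"start": np.int64, "end": np.int64}
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_bedgraph(
    path,
    bin_width: int,
    chrom_sizes: Mapping[str, int] | None = None,
    resample: bool = False,
) -> BinnedTrack:
    """Read a 4-column bedGraph into a :class:`BinnedTrack`.

    Records must be non-overlapping. Bins with no covering record stay
    missing. Records not aligned to the bin grid raise unless ``resample``
    is set, in which case each bin gets the coverage-weighted mean of the
    records overlapping it.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    if (df["start"] < 0).any():
        raise ValueError("negative coordinates in bedGraph")
    if (df["end"] <= df["start"]).any():
        raise ValueError("empty or inverted bedGraph record")
    for chrom, grp in df.groupby("chrom"):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping bedGraph records on {chrom}")
    if chrom_sizes is None:
        chrom_sizes = {c: int(g["end"].max()) for c, g in df.groupby("chrom")}
    track = BinnedTrack(bin_width, dict(chrom_sizes))
    for chrom, grp in df.groupby("chrom"):
        if chrom not in track.data:
            raise ValueError(f"bedGraph chromosome {chrom} not in chrom_sizes")
        v = track.data[chrom]
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        vals = grp["value"].to_numpy()
        aligned = ((starts % bin_width == 0)
                   & ((ends % bin_width == 0)
                      | (ends == track.chrom_sizes[chrom]))).all()
        if aligned and not resample:
            for s, e, x in zip(starts, ends, vals):
                v[s // bin_width: _n_bins(e, bin_width)] = x
        elif not resample:
            raise ValueError(
                "bedGraph records not aligned to the bin grid; "
                "pass resample=True for coverage-weighted resampling"
            )
        else:
            cov = np.zeros_like(v)
            acc = np.zeros_like(v)
            for s, e, x in zip(starts, ends, vals):
                b0, b1 = s // bin_width, _n_bins(e, bin_width)
                for b in range(b0, b1):
                    lo = max(s, b * bin_width)
                    hi = min(e, (b + 1) * bin_width)
                    acc[b] += x * (hi - lo)
                    cov[b] += hi - lo
            with np.errstate(invalid="ignore"):
                v[:] = np.where(cov > 0, acc / np.maximum(cov, 1), np.nan)
    return track


def write_bedgraph(track: BinnedTrack, path, merge_equal: bool = False) -> None:
    """Write non-missing bins as bedGraph records."""
    with open(path, "w") as fh:
        for chrom in track.chrom_sizes:
            v = track.data[chrom]
            size = track.chrom_sizes[chrom]
            idx = np.flatnonzero(~np.isnan(v))
            for i in idx:
                s = i * track.bin_width
                e = min(s + track.bin_width, size)
                fh.write(f"{chrom}\t{s}\t{e}\t{FMT % v[i]}\n")


_SEG_HEADER = ("#chrom\tstart\tend\tname\tscore\tstrand\t"
               "delta_rfd\torientation_flipped\n")


def _chrom_sort_key(name: str):
    # numeric-aware ordering with documented lexicographic fallback
    base = name[3:] if name.startswith("chr") else name
    return (0, int(base), "") if base.isdigit() else (1, 0, name)


def write_segments_bed(segments: Iterable[Segment], path) -> None:
    """Write segments as BED6+2.

    name = kind (or ``kind:as_type``), score = round(1000·|ΔRFD|/2) clipped
    to [0, 1000]; extra columns carry ΔRFD at text precision and the
    orientation flag. Sorted by chromosome then start.
    """
    segs = sorted(segments, key=lambda s: (_chrom_sort_key(s.chrom), s.pos_5p))
    with open(path, "w") as fh:
        fh.write(_SEG_HEADER)
        for s in segs:
            name = s.kind if s.as_type is None else f"{s.kind}:{s.as_type}"
            if math.isnan(s.delta_rfd):
                score, dr = 0, "nan"
            else:
                score = int(np.clip(round(1000 * abs(s.delta_rfd) / 2), 0, 1000))
                dr = FMT % s.delta_rfd
            fh.write(
                f"{s.chrom}\t{s.pos_5p}\t{s.pos_3p}\t{name}\t{score}\t.\t"
                f"{dr}\t{int(s.orientation_flipped)}\n"
            )


def read_segments_bed(path) -> list[Segment]:
    out: list[Segment] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            kind, _, as_type = f[3].partition(":")
            out.append(Segment(
                chrom=f[0], pos_5p=int(f[1]), pos_3p=int(f[2]), kind=kind,
                delta_rfd=float(f[6]), as_type=as_type or None,
                orientation_flipped=bool(int(f[7])),
            ))
    return out


def read_intervals_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), int(f[2])))
    if not rows:
        return empty_intervals()
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).astype(
        {"start": np.int64, "end": np.int64}
    )


def write_intervals_bed(iv: pd.DataFrame, path) -> None:
    iv.sort_values(["chrom", "start"]).to_csv(
        path, sep="\t", header=False, index=False,
        columns=["chrom", "start", "end"],
    )


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return df


def write_gene_table(genes: pd.DataFrame, path) -> None:
    out = genes[GENE_COLUMNS].copy()
    for col in ("exonic_length_kb", "tpm"):
        out[col] = out[col].map(lambda x: float(FMT % x) if pd.notna(x) else x)
    out.to_csv(path, sep="\t", index=False)


def read_rt_table(path, bin_width: int = 10_000,
                  chrom_sizes: Mapping[str, int] | None = None) -> BinnedTrack:
    """Read a 3-column replication-timing TSV (chrom, position, log2 E/L).

    ``position`` is interpreted as the 0-based start of a ``bin_width`` bin
    (a 1-based first column of 1 is tolerated and shifted down).
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "pos", "value"],
                     dtype={"chrom": str, "pos": np.int64, "value": float})
    if len(df) and (df["pos"] % bin_width == 1).all():
        df["pos"] -= 1
    if chrom_sizes is None:
        chrom_sizes = {c: int(g["pos"].max()) + bin_width
                       for c, g in df.groupby("chrom")}
    track = BinnedTrack(bin_width, dict(chrom_sizes))
    for chrom, grp in df.groupby("chrom"):
        track.data[chrom][grp["pos"].to_numpy() // bin_width] = grp["value"].to_numpy()
    return track


def n_gap_mask(fasta_path, min_run: int = 21) -> pd.DataFrame:
    """Locate runs of >= ``min_run`` consecutive N/n in a FASTA.

    Returns a bed-like DataFrame of maximal runs, used to mask unmappable
    sequence when shuffling interval sets.
    """
    from pyfaidx import Fasta

    rows = []
    fa = Fasta(str(fasta_path), rebuild=False, build_index=True)
    for name in fa.keys():
        seq = str(fa[name][:]).upper()
        is_n = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("N")
        if not is_n.any():
            continue
        d = np.diff(np.concatenate(([0], is_n.view(np.int8), [0])))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_run:
                rows.append((name, int(s), int(e)))
    if not rows:
        return empty_intervals()
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).astype(
        {"start": np.int64, "end": np.int64}
    )
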