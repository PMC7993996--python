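"""Synthetic genomes with a planted replication program.

The generator builds chromosomes carrying known initiation zones (IZ),
termination zones (TZ), unidirectionally replicating regions (URR) and
null-RFD regions (NRR), genes with zero-inflated log-normal expression
placed to realize the transcriptional AS types (type 1: expressed genes at
both IZ borders; type 2: one border; non-genic: no gene within 20 kb), a
replication-timing field that is early around genic IZs and late elsewhere,
and H4K20me3 marks on a subset of late non-genic IZs and NRR interiors.

Every downstream stage can then be scored against this planted truth.
The measurement models are:

* OK-seq: per bin, total fragments N ~ Poisson(depth) and reverse-strand
  reads R ~ Binomial(N, (1 + RFD_true)/2), F = N − R;
* ChIP: counts ~ Poisson(depth · accessibility · enrichment) where the
  enrichment multiplies a replication-timing factor (interpolating the
  configured early/late ratio), gene-body depletion within active genes,
  a Gaussian TSS peak at active promoters, and an H4K20me3 boost inside
  marked intervals; the input sample sees accessibility only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BinnedTrack, StrandedBinCounts, empty_intervals

__all__ = [
    "SimConfig",
    "PlantedFeature",
    "SyntheticTruth",
    "build_genome",
    "true_rfd",
    "simulate_okseq",
    "simulate_chip",
    "CHIP_FACTORS",
]

CHIP_FACTORS = ("Orc2", "Orc3", "Mcm3", "Mcm7", "H4K20me1", "H4K20me3", "input")

#: early/late mean-density ratios per factor in G1 and S-G2-M chromatin
RT_RATIO_G1 = {"Orc2": 1.40, "Orc3": 1.47, "Mcm3": 1.15, "Mcm7": 1.19,
               "H4K20me1": 1.0, "H4K20me3": 1.1}
RT_RATIO_S = {"Orc2": 1.18, "Orc3": 1.24, "Mcm3": 1.0, "Mcm7": 1.0,
              "H4K20me1": 1.0, "H4K20me3": 1.1}


@dataclass
class SimConfig:
    """Parameters of the synthetic replication program.

    Identical config + seed produce bit-identical outputs. Depths are mean
    fragments (reads) per bin.
    """

    seed: int = 0
    n_chrom: int = 1
    chrom_length: int = 50_000_000
    bin_width: int = 1_000
    rt_bin_width: int = 10_000
    okseq_depth: float = 100.0
    chip_depth: float = 100.0

    # planted replication architecture
    n_iz: int = 30
    iz_width_range: tuple[float, float] = (30_000, 60_000)
    iz_efficiencies: tuple[float, ...] | None = None  # None: even 0.3..1.0
    n_urr: int = 2
    n_nrr: int = 2
    urr_length: int = 350_000
    nrr_length: int = 550_000
    urr_level: float = 0.9
    iz_plateau: int = 100_000  # flat |RFD| shoulder on both sides of an IZ
    edge_margin: int = 500_000

    # transcription layout
    with_genes: bool = True
    frac_type1: float = 0.25
    frac_type2: float = 0.35
    frac_non_genic: float = 0.25  # remainder becomes genic_other
    n_background_genes: int = 40
    gene_length_range: tuple[float, float] = (35_000, 80_000)
    flank_gap_range: tuple[float, float] = (2_000, 15_000)
    exonic_fraction: float = 0.4
    silent_fraction: float = 0.45       # zero-inflation of background TPM
    tpm_log_mean: float = 3.0           # log-normal component, ln scale
    tpm_log_sd: float = 1.2
    library_reads: int = 2_000_000

    # replication timing field
    rt_early_level: float = 2.5
    rt_late_level: float = -3.0
    rt_bump_sigma: float = 250_000.0

    # ChIP enrichment truth
    rt_ratio: dict[str, float] = field(default_factory=lambda: dict(RT_RATIO_G1))
    rt_ratio_s_phase: dict[str, float] = field(default_factory=lambda: dict(RT_RATIO_S))
    gene_body_depletion: float = 0.6
    tss_peak_amplitude: float = 2.0
    tss_peak_sigma: float = 2_000.0
    h4k20me3_boost: float = 2.0
    mark_track_enrichment: float = 5.0  # H4K20me3's own signal in marked bins
    input_bias_amplitude: float = 1.3   # accessibility lift in early/TSS bins
    h4k20me3_frac_nongenic: float = 0.5
    expressed_tpm: float = 3.0

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        for key in ("iz_width_range", "gene_length_range", "flank_gap_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("iz_efficiencies") is not None:
            d["iz_efficiencies"] = tuple(d["iz_efficiencies"])
        return cls(**d)


@dataclass
class PlantedFeature:
    chrom: str
    start: int
    end: int
    kind: str                     # IZ, TZ, URR, NRR
    efficiency: float = 1.0       # IZ/TZ ramp half-height; URR uses level
    sign: int = 1                 # URR orientation
    as_type: str | None = None    # intended transcriptional type for IZ
    rt_class: str = "late"
    h4k20me3: bool = False

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class SyntheticTruth:
    """Planted architecture plus the parameters of the measurement model."""

    config: SimConfig
    chrom_sizes: dict[str, int]
    features: list[PlantedFeature]
    rt: BinnedTrack
    genes: pd.DataFrame
    h4k20me3_intervals: pd.DataFrame

    def features_of(self, kind: str) -> list[PlantedFeature]:
        return [f for f in self.features if f.kind == kind]


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _assign_as_types(cfg: SimConfig, n: int, rng: np.random.Generator) -> list[str]:
    if not cfg.with_genes:
        return ["non_genic"] * n
    n1 = int(round(cfg.frac_type1 * n))
    n2 = int(round(cfg.frac_type2 * n))
    ng = int(round(cfg.frac_non_genic * n))
    if n1 + n2 + ng > n:
        raise ValueError("AS type fractions exceed 1")
    types = (["type1"] * n1 + ["type2"] * n2 + ["non_genic"] * ng
             + ["genic_other"] * (n - n1 - n2 - ng))
    rng.shuffle(types)
    return types


def _place_gene(occupied: list[tuple[int, int]], start: int, end: int,
                chrom_len: int) -> bool:
    if start < 0 or end > chrom_len:
        return False
    for s, e in occupied:
        if end > s and start < e:
            return False
    occupied.append((start, end))
    return True


def build_genome(cfg: SimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Lay out planted features and genes; derive RT field and marks."""
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.chrom_sizes()
    features: list[PlantedFeature] = []
    gene_rows: list[dict] = []
    mark_rows: list[tuple[str, int, int]] = []
    gene_counter = 0

    for chrom in cfg.chrom_names():
        L = sizes[chrom]
        usable = L - 2 * cfg.edge_margin
        n_slots = cfg.n_iz + cfg.n_nrr
        slot = usable / n_slots
        min_span = (cfg.iz_width_range[1] + 2 * cfg.iz_plateau
                    + cfg.urr_length + cfg.nrr_length)
        if slot < min_span * 0.9:
            raise ValueError(
                "chromosome too short for the requested feature count: "
                f"slot {slot:.0f} bp < required span {min_span:.0f} bp")
        if cfg.iz_efficiencies is not None:
            effs = list(np.resize(cfg.iz_efficiencies, cfg.n_iz))
        else:
            effs = list(np.linspace(0.3, 1.0, cfg.n_iz))
        rng.shuffle(effs)
        as_types = _assign_as_types(cfg, cfg.n_iz, rng)
        # URRs attach directly after these IZ indices; efficiency is forced
        # just below the URR call threshold so the planted URR boundaries
        # are sharp on the true profile
        urr_after = set(rng.choice(cfg.n_iz, size=cfg.n_urr, replace=False)
                        .tolist()) if cfg.n_urr else set()
        nrr_slots = set((np.arange(cfg.n_nrr) * (n_slots // max(cfg.n_nrr, 1))
                         + n_slots // (2 * max(cfg.n_nrr, 1))).tolist())

        occupied: list[tuple[int, int]] = []
        iz_idx = 0
        for s_i in range(n_slots):
            base = cfg.edge_margin + s_i * slot
            if s_i in nrr_slots:
                a = int(base + (slot - cfg.nrr_length) / 2)
                features.append(PlantedFeature(
                    chrom, a, a + cfg.nrr_length, "NRR", rt_class="late"))
                continue
            width = float(rng.uniform(*cfg.iz_width_range))
            jitter = rng.uniform(0.25, 0.55) * slot
            a = int(base + jitter)
            b = int(a + width)
            eff = effs[iz_idx]
            as_type = as_types[iz_idx]
            if iz_idx in urr_after:
                eff = 0.78
            rt_class = "early" if as_type in ("type1", "type2", "genic_other") \
                else "late"
            iz = PlantedFeature(chrom, a, b, "IZ", efficiency=float(eff),
                                as_type=as_type, rt_class=rt_class)
            features.append(iz)
            if iz_idx in urr_after:
                features.append(PlantedFeature(
                    chrom, b + cfg.iz_plateau,
                    b + cfg.iz_plateau + cfg.urr_length, "URR",
                    sign=1, rt_class=rt_class))
            iz_idx += 1

            # flanking genes realizing the intended AS type
            if cfg.with_genes and as_type in ("type1", "type2", "genic_other"):
                sides = {"type1": ("left", "right"),
                         "type2": (("left",) if rng.random() < 0.5
                                   else ("right",)),
                         "genic_other": (("left",) if rng.random() < 0.5
                                         else ("right",))}[as_type]
                expressed = as_type != "genic_other"
                for side in sides:
                    glen = int(rng.uniform(*cfg.gene_length_range))
                    gap = int(rng.uniform(*cfg.flank_gap_range))
                    if side == "left":
                        ge, gs = a - gap, a - gap - glen
                    else:
                        gs, ge = b + gap, b + gap + glen
                    if not _place_gene(occupied, gs, ge, L):
                        raise ValueError(
                            f"cannot place flanking gene at {chrom}:{gs}-{ge}")
                    if expressed:
                        tpm = float(5.0 + rng.lognormal(cfg.tpm_log_mean,
                                                        cfg.tpm_log_sd))
                    else:
                        tpm = float(rng.uniform(0.0, 2.5))
                    gene_counter += 1
                    gene_rows.append(dict(
                        gene_id=f"G{gene_counter:05d}", chrom=chrom,
                        start=gs, end=ge,
                        strand="+" if rng.random() < 0.5 else "-",
                        tpm=tpm))

        # background genes in feature-free space, away from every IZ
        if cfg.with_genes:
            iz_zones = [(f.start - 80_000, f.end + 80_000)
                        for f in features
                        if f.chrom == chrom and f.kind in ("IZ", "URR", "NRR")]
            placed = 0
            for _ in range(cfg.n_background_genes * 20):
                if placed >= cfg.n_background_genes:
                    break
                glen = int(rng.uniform(*cfg.gene_length_range))
                gs = int(rng.uniform(cfg.edge_margin, L - cfg.edge_margin - glen))
                ge = gs + glen
                if any(ge > s and gs < e for s, e in iz_zones):
                    continue
                # keep metaprofile isolation: 16 kb clearance between genes
                if not _place_gene(occupied, gs - 16_000, ge + 16_000, L):
                    continue
                occupied[-1] = (gs, ge)
                if rng.random() < cfg.silent_fraction:
                    tpm = 0.0 if rng.random() < 0.6 else float(rng.uniform(0, 2.5))
                else:
                    tpm = float(3.5 + rng.lognormal(cfg.tpm_log_mean,
                                                    cfg.tpm_log_sd))
                gene_counter += 1
                gene_rows.append(dict(
                    gene_id=f"G{gene_counter:05d}", chrom=chrom,
                    start=gs, end=ge,
                    strand="+" if rng.random() < 0.5 else "-",
                    tpm=tpm))

    # gene table with exonic lengths and TPM-consistent read counts
    if gene_rows:
        genes = pd.DataFrame(gene_rows)
        genes["exonic_length_kb"] = (genes["end"] - genes["start"]) \
            * cfg.exonic_fraction / 1000.0
        weight = genes["tpm"] * genes["exonic_length_kb"]
        total = weight.sum()
        lam = (cfg.library_reads * weight / total).to_numpy() if total > 0 \
            else np.zeros(len(genes))
        genes["read_count"] = rng.poisson(lam)
        genes["activity_class"] = pd.cut(
            genes["tpm"], [-0.1, 3, 10, 40, np.inf],
            labels=["no", "low", "mid", "high"], right=False).astype(str)
    else:
        genes = pd.DataFrame(columns=[
            "gene_id", "chrom", "start", "end", "strand",
            "exonic_length_kb", "read_count", "tpm", "activity_class"])

    # replication-timing field: early Gaussian bumps around early IZs
    rt = BinnedTrack(cfg.rt_bin_width, dict(sizes))
    for chrom in sizes:
        n = rt.n_bins(chrom)
        x = (np.arange(n) + 0.5) * cfg.rt_bin_width
        bump = np.zeros(n)
        for f in features:
            if f.chrom == chrom and f.kind == "IZ" and f.rt_class == "early":
                bump += np.exp(-((x - f.center) ** 2)
                               / (2 * cfg.rt_bump_sigma ** 2))
        rt.data[chrom] = cfg.rt_late_level + \
            (cfg.rt_early_level - cfg.rt_late_level) * np.minimum(bump, 1.0)

    # H4K20me3 marks: subset of late non-genic IZs + NRR interiors
    for f in features:
        if f.kind == "IZ" and f.as_type == "non_genic" and f.rt_class == "late":
            if rng.random() < cfg.h4k20me3_frac_nongenic:
                f.h4k20me3 = True
                mark_rows.append((f.chrom, f.start, f.end))
        elif f.kind == "NRR":
            span = f.end - f.start
            s = f.start + int(0.35 * span)
            e = f.start + int(0.65 * span)
            f.h4k20me3 = True
            mark_rows.append((f.chrom, s, e))
    marks = (pd.DataFrame(mark_rows, columns=["chrom", "start", "end"])
             .astype({"start": np.int64, "end": np.int64})
             if mark_rows else empty_intervals())

    truth = SyntheticTruth(config=cfg, chrom_sizes=dict(sizes),
                           features=features, rt=rt, genes=genes,
                           h4k20me3_intervals=marks)
    return genes, truth


# ---------------------------------------------------------------------------
# true RFD profile
# ---------------------------------------------------------------------------

def _scaled_logistic(x: np.ndarray, a: float, b: float,
                     lo: float, hi: float) -> np.ndarray:
    """Logistic ramp from exactly ``lo`` at ``a`` to ``hi`` at ``b``."""
    m, s = 0.5 * (a + b), (b - a) / 6.0
    raw = 1.0 / (1.0 + np.exp(-(x - m) / s))
    r0 = 1.0 / (1.0 + np.exp(3.0))
    r1 = 1.0 / (1.0 + np.exp(-3.0))
    return lo + (hi - lo) * (raw - r0) / (r1 - r0)


def true_rfd(truth: SyntheticTruth, bin_width: int | None = None) -> BinnedTrack:
    """Deterministic noise-free RFD implied by the planted architecture.

    IZs are logistic ramps from −e to +e flanked by flat shoulders at ±e,
    TZs symmetric descents, URRs pinned at ±urr_level, NRRs pinned at 0
    with guard values just outside their call band at the edges; everything
    between features is linearly interpolated and chromosome ends are
    anchored at 0.
    """
    cfg = truth.config
    w = bin_width or cfg.bin_width
    track = BinnedTrack(w, dict(truth.chrom_sizes))
    for chrom, size in truth.chrom_sizes.items():
        n = track.n_bins(chrom)
        x = (np.arange(n) + 0.5) * w
        v = np.full(n, np.nan)
        feats = sorted((f for f in truth.features if f.chrom == chrom),
                       key=lambda f: f.start)
        for f in feats:
            b0, b1 = int(f.start // w), int(-(-f.end // w))
            b0, b1 = max(b0, 0), min(b1, n)
            if f.kind == "IZ":
                e = f.efficiency
                v[b0:b1] = _scaled_logistic(x[b0:b1], f.start, f.end, -e, e)
                p = int(cfg.iz_plateau // w)
                v[max(0, b0 - p):b0] = -e
                v[b1:min(n, b1 + p)] = e
            elif f.kind == "TZ":
                e = f.efficiency
                v[b0:b1] = _scaled_logistic(x[b0:b1], f.start, f.end, e, -e)
            elif f.kind == "URR":
                lvl = f.sign * cfg.urr_level
                v[b0:b1] = lvl
                guard = f.sign * 0.75
                if b0 > 0 and np.isnan(v[b0 - 1]):
                    v[b0 - 1] = guard
                if b1 < n and np.isnan(v[b1]):
                    v[b1] = guard
            elif f.kind == "NRR":
                v[b0:b1] = 0.0
                if b0 > 0 and np.isnan(v[b0 - 1]):
                    v[b0 - 1] = 0.2
                if b1 < n and np.isnan(v[b1]):
                    v[b1] = -0.2
        # chromosome ends: anchored just outside the NRR call band, with the
        # sign of the nearest planted value, so the edge taper neither
        # fabricates a null-RFD region nor a unidirectional one
        if np.isnan(v).all():
            track.data[chrom] = np.zeros(n)
            continue
        filled0 = np.flatnonzero(~np.isnan(v))
        if np.isnan(v[0]):
            s0 = np.sign(v[filled0[0]]) or 1.0
            v[0] = 0.2 * s0
        if np.isnan(v[-1]):
            s1 = np.sign(v[filled0[-1]]) or -1.0
            v[-1] = 0.2 * s1
        # shape the unset stretches before interpolation: forks leaving a
        # high-|RFD| shoulder decelerate quickly (guard point at 0.75) and
        # zero-crossings are kept sharp so termination gradients are never
        # mistaken for planted URR/NRR stretches
        filled = np.flatnonzero(~np.isnan(v))
        gaps = []
        prev = filled[0]
        for i in filled[1:]:
            if i > prev + 1:
                gaps.append((prev, i))
            prev = i
        for il, ir in gaps:
            vl, vr = v[il], v[ir]
            gap = ir - il
            gl = max(1, min(int(60_000 // w), gap // 4))
            if abs(vl) > 0.75:
                v[il + gl] = np.sign(vl) * 0.75
            if abs(vr) > 0.75:
                v[ir - gl] = np.sign(vr) * 0.75
            if vl * vr < 0 and min(abs(vl), abs(vr)) >= 0.2:
                cw = max(1, min(int(40_000 // w), gap // 6))
                mid = (il + ir) // 2
                v[mid - cw] = np.sign(vl) * 0.2
                v[mid + cw] = np.sign(vr) * 0.2
        idx = np.flatnonzero(~np.isnan(v))
        v = np.interp(np.arange(n), idx, v[idx])
        track.data[chrom] = np.clip(v, -1.0, 1.0)
    return track


# ---------------------------------------------------------------------------
# measurement models
# ---------------------------------------------------------------------------

def simulate_okseq(
    truth: SyntheticTruth,
    depth: float | None = None,
    seed: int | np.random.Generator = 0,
    rfd_true: BinnedTrack | None = None,
) -> StrandedBinCounts:
    """Sample stranded Okazaki-fragment counts from the true RFD.

    Per bin: N ~ Poisson(depth); R ~ Binomial(N, (1 + RFD)/2); F = N − R.
    """
    cfg = truth.config
    depth = cfg.okseq_depth if depth is None else depth
    if depth < 0:
        raise ValueError("depth must be non-negative")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rfd = rfd_true if rfd_true is not None else true_rfd(truth)
    counts = StrandedBinCounts(rfd.bin_width, dict(truth.chrom_sizes))
    for chrom in truth.chrom_sizes:
        p = (1.0 + rfd.data[chrom]) / 2.0
        N = rng.poisson(depth, size=len(p))
        R = rng.binomial(N, np.clip(p, 0, 1))
        counts.R[chrom] = R
        counts.F[chrom] = N - R
    return counts


def _rt_unit(truth: SyntheticTruth, chrom: str, n: int, w: int) -> np.ndarray:
    """Planted RT mapped to [0, 1] between the late and early thresholds.

    Enrichment follows the 100-kb-smoothed timing field: licensing-factor
    density varies on replication-domain scales, so bins inside an early
    (late) timing domain sit exactly at the configured ratio (baseline).
    """
    from .segmentation import smooth_rt

    rt = smooth_rt(truth.rt).data[chrom]
    reps = truth.config.rt_bin_width // w
    if reps >= 1:
        full = np.repeat(rt, reps)[:n]
        if len(full) < n:
            full = np.pad(full, (0, n - len(full)), constant_values=rt[-1])
    else:
        step = w // truth.config.rt_bin_width
        full = rt[::step][:n]
    return np.clip((full - (-2.0)) / (1.6 - (-2.0)), 0.0, 1.0)


def enrichment_profile(
    truth: SyntheticTruth,
    factor: str,
    phase: str = "G1",
    bin_width: int | None = None,
) -> BinnedTrack:
    """Noise-free per-bin enrichment (and accessibility for 'input')."""
    cfg = truth.config
    if factor not in CHIP_FACTORS:
        raise ValueError(f"unknown ChIP factor {factor!r}")
    if phase not in ("G1", "S-G2-M"):
        raise ValueError("phase must be 'G1' or 'S-G2-M'")
    w = bin_width or cfg.rt_bin_width
    out = BinnedTrack(w, dict(truth.chrom_sizes))
    ratios = cfg.rt_ratio if phase == "G1" else cfg.rt_ratio_s_phase
    genes = truth.genes
    for chrom, size in truth.chrom_sizes.items():
        n = out.n_bins(chrom)
        centers = (np.arange(n) + 0.5) * w
        u = _rt_unit(truth, chrom, n, w)
        acc = 1.0 + (cfg.input_bias_amplitude - 1.0) * u
        tss_g = np.zeros(n)
        body = np.zeros(n, dtype=bool)
        if len(genes):
            for _, g in genes[genes["chrom"] == chrom].iterrows():
                if float(g["tpm"]) < cfg.expressed_tpm:
                    continue
                tss = int(g["start"]) if g["strand"] == "+" else int(g["end"])
                near = np.abs(centers - tss) < 6 * cfg.tss_peak_sigma
                tss_g[near] = np.maximum(
                    tss_g[near],
                    np.exp(-((centers[near] - tss) ** 2)
                           / (2 * cfg.tss_peak_sigma ** 2)))
                body |= (centers >= int(g["start"])) & (centers < int(g["end"]))
        acc *= 1.0 + (cfg.input_bias_amplitude - 1.0) * tss_g
        if factor == "input":
            out.data[chrom] = acc
            continue
        enrich = 1.0 + (ratios.get(factor, 1.0) - 1.0) * u
        if factor in ("Orc2", "Orc3", "Mcm3", "Mcm7"):
            base = np.where(body, cfg.gene_body_depletion, 1.0)
            bt = base + (cfg.tss_peak_amplitude - base) * tss_g
            enrich = enrich * bt
            if len(truth.h4k20me3_intervals):
                m = truth.h4k20me3_intervals
                for _, r in m[m["chrom"] == chrom].iterrows():
                    sel = (centers >= r["start"]) & (centers < r["end"])
                    enrich[sel] *= cfg.h4k20me3_boost
        elif factor == "H4K20me3":
            if len(truth.h4k20me3_intervals):
                m = truth.h4k20me3_intervals
                for _, r in m[m["chrom"] == chrom].iterrows():
                    sel = (centers >= r["start"]) & (centers < r["end"])
                    enrich[sel] *= cfg.mark_track_enrichment
        out.data[chrom] = acc * enrich
    return out


def simulate_chip(
    truth: SyntheticTruth,
    factor: str,
    phase: str = "G1",
    depth: float | None = None,
    seed: int | np.random.Generator = 0,
    bin_width: int | None = None,
) -> BinnedTrack:
    """Poisson ChIP (or input) read counts under the planted enrichment."""
    cfg = truth.config
    depth = cfg.chip_depth if depth is None else depth
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    lam = enrichment_profile(truth, factor, phase, bin_width)
    out = BinnedTrack.like(lam)
    for chrom in out.chrom_sizes:
        out.data[chrom] = rng.poisson(depth * lam.data[chrom]).astype(float)
    return out
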