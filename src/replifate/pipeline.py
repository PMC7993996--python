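"""End-to-end orchestration of the synthetic replication-program analysis.

Runs simulate → RFD → segmentation → constant-RFD → RTD → ChIP
normalization → TPM/window categories → AS typing / mark subsetting →
aggregates → recovery scoring, writing every intermediate plus a manifest
(inputs, parameters, seed, output hashes) so a rerun with the same config
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregate import gene_metaprofile, rt_decile_hist2d, welch_t_one_sided
from .chip import input_normalize, normalize_mean, zero_input_mask
from .core import (BinnedTrack, Segment, write_bedgraph, write_gene_table,
                   write_segments_bed)
from .regions import (classify_as, genes_exclusion_zone, interval_bin_mask,
                      region_mean_frequency, segments_to_intervals,
                      subset_by_mark)
from .rfd import compute_rfd, pool_replicates, rebin_counts
from .segmentation import (ConvexitySettings, detect_constant_rfd,
                           detect_rtds, detect_segments, filter_segments,
                           smooth_convexity, smooth_rt)
from .simulate import SimConfig, SyntheticTruth, build_genome, simulate_chip, \
    simulate_okseq, true_rfd
from .transcription import categorize_windows, compute_tpm

log = logging.getLogger("replifate")

__all__ = ["run_pipeline", "score_iz_recovery", "stage_rng"]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named substream: every stage draws from its own child of the root seed."""
    digest = hashlib.sha256(stage.encode()).digest()
    sub = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, sub]))


def score_iz_recovery(
    detected_as: list[Segment],
    truth: SyntheticTruth,
    tolerance: float = 32_000.0,
    min_efficiency: float = 0.0,
) -> dict:
    """Match detected ascending segments against planted initiation zones.

    A planted IZ is recovered when a detected AS midpoint lies within
    ``tolerance`` of its center (each AS matches at most one IZ). Returns
    precision/recall restricted to IZs with efficiency >= min_efficiency,
    plus per-IZ match details (midpoint offset, ΔRFD error vs planted 2e).
    """
    izs = [f for f in truth.features_of("IZ")
           if f.efficiency >= min_efficiency]
    used = set()
    rows = []
    for f in izs:
        best, best_d = None, tolerance
        for i, seg in enumerate(detected_as):
            if i in used or seg.chrom != f.chrom:
                continue
            d = abs(seg.midpoint - f.center)
            if d <= best_d:
                best, best_d = i, d
        if best is not None:
            used.add(best)
            seg = detected_as[best]
            rows.append({
                "chrom": f.chrom, "center": f.center,
                "efficiency": f.efficiency, "recovered": True,
                "midpoint_offset": seg.midpoint - f.center,
                "delta_rfd_error": seg.delta_rfd - 2 * f.efficiency,
            })
        else:
            rows.append({"chrom": f.chrom, "center": f.center,
                         "efficiency": f.efficiency, "recovered": False,
                         "midpoint_offset": np.nan,
                         "delta_rfd_error": np.nan})
    detail = pd.DataFrame(rows)
    n_match = int(detail["recovered"].sum())
    all_centers = [(f.chrom, f.center) for f in truth.features_of("IZ")]
    fp = sum(
        1 for seg in detected_as
        if not any(c == seg.chrom and abs(seg.midpoint - x) <= tolerance
                   for c, x in all_centers))
    recall = n_match / len(izs) if izs else np.nan
    precision = ((len(detected_as) - fp) / len(detected_as)
                 if detected_as else np.nan)
    return {"recall": recall, "precision": precision,
            "n_planted": len(izs), "n_detected": len(detected_as),
            "false_positives": fp, "detail": detail}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: SimConfig, outdir: str | Path,
                 chip_factors: tuple[str, ...] = ("Orc2", "Mcm3"),
                 settings: ConvexitySettings | None = None) -> dict:
    """Execute every stage on a synthetic genome; return the manifest."""
    t0 = time.time()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def stage(name: str):
        log.info("stage %s", name)
        stages.append({"stage": name, "t": round(time.time() - t0, 3)})

    # 1. simulate
    stage("simulate")
    genes, truth = build_genome(config)
    rfd_true = true_rfd(truth)
    write_gene_table(genes, out / "genes.tsv")
    counts = simulate_okseq(truth, seed=stage_rng(config.seed, "okseq"),
                            rfd_true=rfd_true)
    chip_raw = {}
    for factor in (*chip_factors, "input"):
        chip_raw[factor] = simulate_chip(
            truth, factor, "G1", seed=stage_rng(config.seed, f"chip:{factor}"))

    # 2. RFD
    stage("rfd")
    pooled = pool_replicates([counts])
    rfd = compute_rfd(pooled)
    write_bedgraph(rfd, out / "rfd.bedgraph")

    # 3-4. segmentation and constant RFD
    stage("segment")
    settings = settings or ConvexitySettings()
    conv = smooth_convexity(rfd, settings)
    as_raw, ds_raw = detect_segments(conv, rfd, settings)
    as_filt = filter_segments(as_raw)
    ds_filt = filter_segments(ds_raw, use_abs=True)
    # constant-RFD regions are called on 10-kb window-summed RFD: bin-level
    # sampling noise would break long homogeneous runs at realistic depth
    stage("constant-rfd")
    rfd10 = compute_rfd(rebin_counts(pooled, 10_000))
    urrs = detect_constant_rfd(rfd10, "URR")
    nrrs = detect_constant_rfd(rfd10, "NRR")

    # 5. RTDs
    stage("rtd")
    rt_s = smooth_rt(truth.rt)
    early_rtds, late_rtds = detect_rtds(rt_s)

    # 6. ChIP normalization
    stage("chip-norm")
    mask = zero_input_mask(chip_raw["input"])
    input_norm = normalize_mean(chip_raw["input"])
    rel = {}
    for factor in chip_factors:
        norm = normalize_mean(chip_raw[factor])
        rel[factor] = input_normalize(norm, input_norm, mask)
        write_bedgraph(rel[factor], out / f"chip_{factor}_rel.bedgraph")

    # 7. transcription
    stage("tpm")
    genes = genes.copy()
    if len(genes) and genes["read_count"].sum() > 0:
        genes["tpm_recomputed"] = compute_tpm(
            genes["read_count"], genes["exonic_length_kb"])
    categories = categorize_windows(truth.rt, genes)

    # 8. classification
    stage("classify")
    as_typed = classify_as(as_filt, genes)
    mark_track = rel.get("H4K20me3")
    subsets = None
    if mark_track is not None:
        non_genic = [s for s in as_typed if s.as_type == "non_genic"]
        if non_genic:
            high, low, neither = subset_by_mark(non_genic, mark_track)
            subsets = {"high": len(high), "low": len(low),
                       "neither": len(neither)}
    all_segments = as_typed + ds_filt + urrs + nrrs + early_rtds + late_rtds
    write_segments_bed(all_segments, out / "segments.bed")

    # 9. aggregates
    stage("aggregate")
    excl = genes_exclusion_zone(genes, pad=10_000)
    rtd_classes = {"early": segments_to_intervals(early_rtds),
                   "late": segments_to_intervals(late_rtds)}
    region_stats = {}
    for factor in chip_factors:
        try:
            res = region_mean_frequency(rtd_classes, rel[factor], excl,
                                        ratio_between=("early", "late"))
            region_stats[factor] = res["ratio"]
        except ValueError:
            region_stats[factor] = np.nan
    hist = rt_decile_hist2d(rel[chip_factors[0]], rt_s)
    np.savetxt(out / "hist2d.tsv", hist["hist"], delimiter="\t", fmt="%.6g")

    # 10. statistics and recovery
    stage("stats")
    f0 = chip_factors[0]
    early_mask = interval_bin_mask(rel[f0], rtd_classes["early"])
    late_mask = interval_bin_mask(rel[f0], rtd_classes["late"])
    ev = np.concatenate([rel[f0].data[c][early_mask[c]]
                         for c in rel[f0].chrom_sizes])
    lv = np.concatenate([rel[f0].data[c][late_mask[c]]
                         for c in rel[f0].chrom_sizes])
    ev, lv = ev[np.isfinite(ev)], lv[np.isfinite(lv)]
    if len(ev) > 1 and len(lv) > 1:
        tstat, pval = welch_t_one_sided(ev, lv, "greater")
    else:
        tstat = pval = np.nan
    recovery = score_iz_recovery(as_typed, truth)
    recovery["detail"].to_csv(out / "recovery.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": stages,
        "counts": {
            "AS_detected": len(as_raw), "AS_filtered": len(as_filt),
            "DS_detected": len(ds_raw), "DS_filtered": len(ds_filt),
            "URR": len(urrs), "NRR": len(nrrs),
            "RTD_early": len(early_rtds), "RTD_late": len(late_rtds),
            "genes": len(genes),
            "as_types": {t: sum(1 for s in as_typed if s.as_type == t)
                         for t in ("type1", "type2", "non_genic",
                                   "genic_other")},
            "h4k20me3_subsets": subsets,
        },
        "recovery": {k: (float(v) if isinstance(v, (int, float, np.floating))
                         else v)
                     for k, v in recovery.items() if k != "detail"},
        "early_late_ratio": {k: (None if not np.isfinite(v) else float(v))
                             for k, v in region_stats.items()},
        "welch_early_gt_late": {"t": None if np.isnan(tstat) else float(tstat),
                                "p": None if np.isnan(pval) else float(pval)},
    }
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir())
        if p.is_file() and p.suffix in (".tsv", ".bed", ".bedgraph")
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
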