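import numpy as np
import pytest

from replifate.core import BinnedTrack, StrandedBinCounts
from replifate.simulate import SimConfig, build_genome, true_rfd


def make_track(values, bin_width=1000, chrom="chr1"):
    """BinnedTrack over a single chromosome from a value vector."""
    v = np.asarray(values, dtype=float)
    return BinnedTrack(bin_width, {chrom: len(v) * bin_width},
                       {chrom: v.copy()})


def make_counts(R, F, bin_width=1000, chrom="chr1"):
    R = np.asarray(R, dtype=np.int64)
    F = np.asarray(F, dtype=np.int64)
    return StrandedBinCounts(bin_width, {chrom: len(R) * bin_width},
                             R={chrom: R}, F={chrom: F})


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale synthetic genome: 14 Mb, 8 IZs, 1 URR, 1 NRR."""
    return SimConfig(seed=11, chrom_length=14_000_000, n_iz=8,
                     n_urr=1, n_nrr=1, n_background_genes=15)


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    genes, truth = build_genome(small_cfg)
    return genes, truth


@pytest.fixture(scope="session")
def small_rfd(small_genome):
    _, truth = small_genome
    return true_rfd(truth)


@pytest.fixture(scope="session")
def flat_cfg():
    """Config with every enrichment switched off: homogeneous ChIP truth."""
    return SimConfig(
        seed=5, chrom_length=14_000_000, n_iz=8, n_urr=1, n_nrr=1,
        n_background_genes=15,
        rt_ratio={f: 1.0 for f in
                  ("Orc2", "Orc3", "Mcm3", "Mcm7", "H4K20me1", "H4K20me3")},
        gene_body_depletion=1.0, tss_peak_amplitude=1.0,
        h4k20me3_boost=1.0, mark_track_enrichment=1.0,
        input_bias_amplitude=1.0)
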