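"""Gene expression quantification and gene-relative window categories.

TPM for gene j is ``1e6 * (n_j / l_j) / sum_i (n_i / l_i)`` with ``n`` the
exonic read count and ``l`` the exonic length in kb; TPM sums to 1e6 over a
sample. Activity classes follow the 3/10/40 cutoffs: no (<3), low (3–10),
mid (10–40), high (>40); the ambiguous boundary values are resolved
lower-inclusive, so exactly 3 is "low" (expressed), exactly 10 "mid",
exactly 40 "high".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import BinnedTrack

__all__ = [
    "compute_tpm",
    "classify_expression",
    "add_expression_classes",
    "categorize_windows",
    "WINDOW_CATEGORIES",
]

EXPRESSION_BOUNDS = (3.0, 10.0, 40.0)
EXPRESSION_CLASSES = ("no", "low", "mid", "high")

WINDOW_CATEGORIES = ("intergenic", "silent_body", "expressed_body", "excluded")
#: integer codes used in category arrays
CAT_INTERGENIC, CAT_SILENT, CAT_EXPRESSED, CAT_EXCLUDED = range(4)


def compute_tpm(read_counts, exonic_lengths_kb) -> np.ndarray:
    """Transcripts per kilobase per million from exonic counts and lengths."""
    n = np.asarray(read_counts, dtype=float)
    l = np.asarray(exonic_lengths_kb, dtype=float)
    if (l <= 0).any():
        raise ValueError("exonic lengths must be positive")
    if (n < 0).any():
        raise ValueError("read counts must be non-negative")
    rates = n / l
    total = rates.sum()
    if total <= 0:
        raise ValueError("all-zero read counts")
    return 1e6 * rates / total


def classify_expression(tpm) -> np.ndarray:
    """Map TPM to activity class: no [0,3), low [3,10), mid [10,40), high [40,inf)."""
    t = np.atleast_1d(np.asarray(tpm, dtype=float))
    if (t < 0).any():
        raise ValueError("TPM must be non-negative")
    idx = np.searchsorted(EXPRESSION_BOUNDS, t, side="right")
    return np.array(EXPRESSION_CLASSES, dtype=object)[idx]


def add_expression_classes(genes: pd.DataFrame,
                           tpm_column: str = "tpm") -> pd.DataFrame:
    out = genes.copy()
    out["activity_class"] = classify_expression(out[tpm_column].to_numpy())
    return out


def categorize_windows(
    geometry: BinnedTrack,
    genes: pd.DataFrame,
    intergenic_distance: int = 5_000,
    body_margin: int = 3_000,
    expressed_tpm: float = 3.0,
) -> dict[str, np.ndarray]:
    """Classify every bin as intergenic, silent/expressed gene body, or excluded.

    A window is intergenic when every gene is more than
    ``intergenic_distance`` away, and a (silent/expressed) gene body window
    when it lies fully inside a gene with TPM below/at-or-above
    ``expressed_tpm`` and more than ``body_margin`` from both gene ends.
    Windows matching neither rule — gene-proximal, border-straddling, or
    inside overlapping genes with conflicting activity — are excluded, which
    drops TSS/TTS-proximal signal by construction.

    Returns per-chromosome integer arrays using the ``CAT_*`` codes.
    """
    w = geometry.bin_width
    out: dict[str, np.ndarray] = {}
    for chrom in geometry.chrom_sizes:
        n = geometry.n_bins(chrom)
        starts = np.arange(n, dtype=np.int64) * w
        ends = np.minimum(starts + w, geometry.chrom_sizes[chrom])
        near_any = np.zeros(n, dtype=bool)
        body_silent = np.zeros(n, dtype=bool)
        body_expressed = np.zeros(n, dtype=bool)
        for _, g in genes[genes["chrom"] == chrom].iterrows():
            gs, ge = int(g["start"]), int(g["end"])
            near = (ends >= gs - intergenic_distance) & \
                   (starts <= ge + intergenic_distance)
            near_any |= near
            inside = (starts - gs > body_margin) & (ge - ends > body_margin)
            if float(g["tpm"]) >= expressed_tpm:
                body_expressed |= inside
            else:
                body_silent |= inside
        cat = np.full(n, CAT_EXCLUDED, dtype=np.int8)
        cat[~near_any] = CAT_INTERGENIC
        only_silent = body_silent & ~body_expressed
        only_expressed = body_expressed & ~body_silent
        cat[only_silent] = CAT_SILENT
        cat[only_expressed] = CAT_EXPRESSED
        # conflicting overlap stays excluded
        out[chrom] = cat
    return out
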