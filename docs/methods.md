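# Methods

## Fork directionality and its segmentation

OK-seq measures, per genomic bin, the counts `R` and `F` of
Okazaki-fragment reads on the reverse and forward strand. Because the
Okazaki fragments of a rightward-moving fork map to the reverse strand,
`RFD = (R − F)/(R + F)` estimates the excess of rightward over leftward
fork passages at the locus; the estimate is undefined (missing) in bins
with `R + F` below `min_total` (default 1 — no cutoff beyond emptiness).
Bin-level RFD is computed on 1-kb bins by default; the bin width is
configurable, and ratio-level quantities derived from windows (the
replicate QC, constant-RFD calling at realistic depth) recompute RFD from
window-summed counts rather than averaging bin RFDs, since the quantity
is a ratio of sums.

Initiation zones appear as quasi-linear ascending stretches of RFD
10–100 kb wide. They are delineated from the convexity of the smoothed
profile: the RFD vector is convolved with the second derivative of a
Gaussian of standard deviation σ = 32 kb (truncated at ±4σ,
mean-subtracted so the discrete kernel sums to zero). A rising ramp
produces a positive convexity extremum at its foot and a negative one at
its shoulder; each maximal positive→negative extremum pair bounds one
ascending segment (AS), negative→positive pairs bound descending
segments (DS). Runs of same-sign super-threshold extrema collapse to the
largest. Borders are placed at extremum positions (not zero-crossings);
this is one of two defensible conventions and is stated here because it
shifts borders by a fraction of σ.

Two numerical choices guard this transform:

* **Gap handling.** Missing runs of ≤10 bins are bridged by linear
  interpolation; longer gaps leave the region missing and split the
  chromosome into independent detection domains. Convexity is only
  emitted where the kernel fully overlaps data, so domain edges cannot
  fabricate extrema.
* **Amplitude threshold.** The extremum amplitude cutoff defaults to
  2 × the robust SD (1.4826 · MAD) of the genome-wide convexity track.
  A fixed absolute threshold is available (`amplitude_threshold_mode =
  "absolute"`); the robust default is scale-free and reproducible while
  keeping the intent of a conservative hand-set cutoff.

Each segment carries `ΔRFD = RFD(pos₃′) − RFD(pos₅′)` with the border
RFD estimated as the mean over one σ just outside the segment — single
border bins are too noisy at realistic depth, and the flank mean is the
simplest stable estimator of the plateau level. Downstream analyses keep
ASs with length > 20 kb (strict) and ΔRFD > 0.5 (strict); DSs use the
symmetric |ΔRFD| rule behind a flag.

Constant-fork-direction calling scans for maximal runs where every bin
satisfies |RFD| > 0.8 (unidirectionally replicating regions, URR,
minimum 300 kb) or |RFD| < 0.15 (null-RFD regions, NRR, minimum 500 kb);
missing bins break runs. The URR condition is applied to the RFD level
itself, not to a segment shift: a flat unidirectional stretch has
near-zero ΔRFD by construction, so the level is the only self-consistent
reading. At depth ~100 fragments/kb the bin-level noise (SD ≈ 0.04)
breaks long runs by chance, so the pipeline calls URR/NRR on 10-kb
window-summed RFD, where the noise SD drops ~3-fold.

## Replication timing

Timing enters as a log₂(Early/Late) track on 10-kb bins. Each bin is
smoothed to the mean of the non-missing values in its surrounding 100-kb
window; with an even number of bins in the window the asymmetry is
resolved deterministically to the lower side (bins i−5…i+4). Early and
late replication-timing domains (RTDs) are maximal runs above 1.6 /
below −2.0 (strict); a `merge_gap` option can merge domains separated by
short gaps but is off by default, so the domain counts reported are
pre-merging counts.

## ChIP normalization chain

Replicate counts are summed per bin (read frequency), divided by the
genome-wide mean over full bins (normalized read frequency, mean exactly
1), and divided by the equally normalized input after masking bins with
zero raw input reads (relative read frequency). The zero-input mask is
computed once per analysis run and applied to every factor so all tracks
share one bin set. Whether the normalization mean includes zero-count
bins is not canonical; they are included here (they are observations,
not missing data). Both input-divided and non-divided analyses are
supported — input division is a robustness axis, not a fixed choice.
For aggregate profiles the input division happens **after** averaging
(ratio of mean profiles); the mean-of-ratios alternative is available
behind a flag. Uncertainty bands are ±2 SEM throughout, with the
sample-track SEM propagated through the input division.

A real-data adapter assigns a read to the bin containing its 5′
position, with no fragment extension — extension is a browser-display
convention, not a quantification one. This choice matters only for
real-data reuse; the synthetic generator works at bin level.

## Transcription

TPM for gene j is `1e6 · (n_j/l_j) / Σ_i (n_i/l_i)` with `l` the exonic
length in kb. Activity classes cut at 3/10/40 TPM; the boundary values
are assigned lower-inclusive (exactly 3 → "low", i.e. expressed), one
consistent rule where the conventional wording ("<3", ">3") leaves the
boundary open. Per-replicate TPMs are averaged rather than computed on
pooled counts. Window categorization calls a 10-kb window intergenic when
every gene is more than 5 kb away, a silent/expressed body window when it
is fully inside a gene (TPM < 3 / ≥ 3) and more than 3 kb from both gene
ends, and excludes everything else — TSS/TTS-proximal signal drops out by
construction. Strands are ignored for the distance rules.

## AS typing and mark subsetting

An AS extended by 20 kb on both sides that overlaps no annotated gene is
non-genic. Among genic ASs, a border qualifies when at least one
transcribed gene (TPM > 3) body lies within 20 kb of the border
coordinate on the outward side or overlapping the flank: both borders →
type 1, exactly one → type 2 (oriented so the transcribed side is the
right border), neither → an explicit `genic_other` label rather than a
silent drop, so class counts always sum to the AS total.

Mark-level subsetting compares each interval's mean relative read
frequency with the genome mean μ and SD s of the mark track: high if
m > μ + 1.5s, low if m < μ, neither otherwise — a deliberate three-way
partition with a gap between the rules. For window-level variants μ and
s are recomputed over the same window universe being subset.

## Statistics

Welch's one-sided t (Satterthwaite df) and one-way ANOVA with Tukey HSD
(95% family-wise) are used for group comparisons; distribution
comparisons report the two-sample KS distance with the sample-size
correction `Z = D·√(nm/(n+m))`, which puts comparisons of different bin
counts on one scale. When both groups are constant and equal the
one-sided t test is undefined and p = 0.5 is returned by convention.

## Shuffling null

Interval sets are shuffled per chromosome, preserving counts and lengths
exactly and avoiding assembly gaps (runs of >20 consecutive N). Starts
are drawn uniformly from the exact admissible set (the complement of the
mask, shrunk by the interval length), so the draw is exactly uniform and
a single admissible slot is always found; self-overlap among placed
intervals is allowed by default (a `--no-self-overlap` mode adds
rejection with whole-draw restarts). Aggregate RFD profiles around
interval centers report the across-interval mean with a 95% envelope;
the envelope defaults to mean ± 1.96·SD/√n (standard error), with a
mean ± 1.96·SD alternative, since either reading of "based on the mean
and standard deviation" is defensible. Envelope coverage statements are
only stable when many shuffle draws are pooled: a single draw shares one
common offset across all profile positions.

## The synthetic genome

The generator is the package's ground truth, not a fixture. Per
chromosome (default: one chromosome of 50 Mb at 1-kb bins) it plants:

* **30 IZs** with efficiencies e spread evenly over 0.3–1.0 and widths
  30–60 kb. The true RFD rises through an IZ as a logistic ramp from −e
  to +e (scale = width/6), so the planted ΔRFD is exactly 2e, flanked by
  flat shoulders at ±e (100 kb) so the flank-mean ΔRFD estimator reads
  the plateau.
* **URRs** (350 kb at |RFD| = 0.9) attached after an IZ whose efficiency
  is forced to 0.78, and **NRRs** (550 kb at RFD = 0) mid-gap; both get
  guard values just outside their call bands at the edges (0.75 / ±0.2)
  so the planted boundaries are sharp to within one bin. Between
  features the profile interpolates linearly, with steep guard descents
  out of |RFD| > 0.75 shoulders and sharpened zero-crossings so that
  termination gradients are never long enough to mimic a planted URR or
  NRR; chromosome ends are anchored just outside the NRR band.
* **Genes** realizing the AS types by construction: type-1 IZs get
  expressed flanking genes (TPM drawn as 5 + log-normal) 2–15 kb outside
  both borders, type-2 one side, `genic_other` a silent neighbor,
  non-genic IZs a ≥80-kb clearance. Background genes (length 35–80 kb,
  mutually isolated by ≥16 kb so metagene eligibility is non-trivial)
  carry zero-inflated log-normal TPM. Read counts are Poisson draws
  consistent with the true TPM, so TPM recomputation recovers the truth.
* **Replication timing** as a smooth field: late baseline −3.0 lifted to
  +2.5 by Gaussian bumps (σ = 250 kb) around genic ("early") IZs;
  non-genic IZs stay late. ChIP enrichment follows the
  **100-kb-smoothed** timing mapped linearly onto [0, 1] between the
  late (−2.0) and early (+1.6) domain thresholds — enrichment varies on
  domain scales, and bins inside a called early/late RTD sit exactly at
  the configured ratio/baseline, which makes enrichment-ratio recovery
  an exact target rather than an approximate one.
* **H4K20me3 marks** on ~half of the late non-genic IZs and on NRR
  interiors (central 30%).

Measurement models: OK-seq counts are `N ~ Poisson(depth)` per bin with
`R ~ Binomial(N, (1 + RFD)/2)`; ChIP counts are
`Poisson(depth · accessibility · enrichment)` where enrichment multiplies
the RT factor (default early/late ratios per factor: Orc2 1.40,
Orc3 1.47, Mcm3 1.15, Mcm7 1.19 in G1; MCM ratios flatten to 1.0 in
S-G2-M chromatin), gene-body depletion (0.6) inside active genes, a
Gaussian TSS peak (amplitude 2.0, σ = 2 kb, blended so the apex reaches
the full amplitude rather than multiplying the depletion), and an
H4K20me3 boost (2.0) for ORC/MCM inside marked intervals. The input
sample sees accessibility only (amplitude 1.3, elevated in early-RT and
TSS bins), so input division cancels accessibility exactly.

What the generator does **not** emulate: mappability and GC biases,
PCR duplicates, fragment-length effects, copy-number variation,
cell-cycle heterogeneity, the continuous spectrum of real RT values
(outside bump flanks the synthetic field is nearly two-valued, so RT
deciles on synthetic data contain ties), and any sequence-level signal.
Passing recovery tests therefore demonstrates correctness of the
*computations* under a faithful count-noise model, not robustness to
every artifact of real libraries.

## Recovery experiments and their problem sizes

The shipped tests and the acceptance script run at desk scale, chosen as
the smallest sizes at which the estimators are comfortably inside their
asymptotic regime: one 50-Mb chromosome (tests of individual modules use
14-Mb genomes), OK-seq depth 100 fragments/bin, ChIP depth 100
reads/10-kb bin, 10⁴ replicates for the statistical-calibration nulls
and 10⁴ draws for the shuffle-uniformity check. Enrichment-parameter
recovery measures the early/late ratio on intergenic bins with genes
±10 kb **and planted H4K20me3 intervals excluded** — the mark boost is a
known confounder of the RT effect, and the recovery experiment controls
for it; gene-body depletion is read from the TSS metagene as the
interior (≥8 kb beyond the TSS, clear of the TSS peak) over flank
(≤−8 kb) ratio.

## Known limitations

* Segment borders at convexity extrema are systematically a fraction of
  σ outside the true ramp ends; border-sensitive statistics inherit
  this convention.
* Bin-level URR/NRR calling is noise-limited below ~1000 reads per
  qualifying window; the 10-kb pipeline default handles depth ≥50/kb.
* `categorize_windows` and gene placement loop over genes in Python;
  fine for annotation sizes up to ~10⁵ genes, not optimized beyond.
* The RT-decile histogram assumes a continuous timing distribution;
  heavily tied tracks collapse deciles and leave reported-empty columns.
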