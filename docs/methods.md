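# Methods

## Screen arm

**Demultiplexing.** Reads are assigned to shRNAs alignment-free: a read
passes QC iff it is at least `min_length` long (default: long enough to
cover the barcode region, which starts at a configurable offset, default 0)
and its barcode region matches exactly one library barcode within
`max_mismatches`. The default is exact matching (`max_mismatches = 0`),
treating any non-library barcode as a "non-existing" sequence; a
one-mismatch mode resolves reads through the 3L-variant substitution
neighborhood, and a general mode falls back to a full Hamming scan (slow,
intended for small libraries). Reads matching ≥ 2 barcodes at equal best
distance are discarded as ambiguous and tallied separately. Because
generated libraries guarantee pairwise barcode distance ≥ 3, one-mismatch
assignment is never ambiguous on synthetic data.

**Normalization and ratios.** Raw counts are scaled per sample to reads per
million (sample depths differ by ~10% in practice, so unnormalized counts
are not comparable). Clone-size ratio: r = (rpm_treated + c)/(rpm_control + c)
with pseudocount c = 0.5. The symmetric pseudocount keeps ratios finite at
zero counts and makes swapping treated and control map r to exactly 1/r, so
enriched and depleted are exact mirror classes. Thresholds are strict
(> 2, < 0.5); a ratio of exactly 2.0 or 0.5 is neutral. A gene is a hit in a
direction when ≥ `min_support` (default 2) of its shRNAs share that class;
both directions can be awarded independently. Two treatment doses are
analyzed independently against the shared DMSO control; an optional
consensus mode intersects (gene, direction) calls across doses but is off
by default since no combination rule is established.

## Expression arm

**VST.** The exact bead-array variance-stabilizing fit needs within-array
bead-level variances that a plain intensity matrix does not carry, so the
default transform is the started log `log2(x + c)`, c = 1 — monotone and
variance-flattening, which is all the downstream threshold filters rely
on. A custom transform can be plugged in.

**Loess normalization.** Each array is corrected against the gene-wise mean
pseudo-array, MA-style: the loess fit (lowess, span 0.3) of
(array − pseudo-array) on the pseudo-array is subtracted, removing
intensity-dependent bias; after correction the residual trend versus mean
intensity is flat.

**Batch correction.** Per gene, each batch's mean (and SD, unless
`mean_only`) is mapped onto the pooled per-gene moments. No empirical-Bayes
shrinkage by default: with one cell line and a handful of samples per
batch the shrinkage prior is under-determined. The pooled per-gene mean is
preserved exactly; a single batch passes through unchanged; singleton
batches are an error unless explicitly allowed.

**Fold changes.** Replicate columns are averaged on the log₂ scale;
the control reference is the matched-time DMSO column when one exists,
otherwise the pooled control mean (logged). Ratios are
2^(log₂ treated_t − log₂ control_t).

**Temporal filters.** Serial regulation: some window of ≥ 4 consecutive
treatment points with every ratio strictly > 1.2 (up) or strictly < 0.8
(down). The 1.2/0.8 pair is deliberately asymmetric (1/1.2 ≈ 0.833 ≠ 0.8)
and taken verbatim; a symmetric-bounds mode (1.2, 1/1.2) exists, and only
in that mode is the r ↦ 1/r direction anti-symmetry exact. The longest
qualifying run is reported, ties going to the earlier start, then up.
Rescue reversal: no qualifying same-direction run in the rescue
trajectory. Non-rescue flatness: sample SD (ddof 1) of the log₂ fold
changes at the last treatment point plus all rescue points ≤ 0.01 — the
0.01 magnitude is only plausible on the ratio/log scale, so the rule is
applied to log₂ fold changes (a config switch accepts other value
vectors). Temporal correlation: Pearson R of the log₂ treatment fold
changes against the time-point index 0..8 (indices rather than raw or log
minutes by default — both alternatives can be passed by building the index
vector accordingly); zero-variance profiles are classified `none` with a
warning. Pathway trajectories average member genes' log₂ ratios per time
point and report each pathway's maximum absolute mean log₂ ratio.

## Integration

Consolidation is a set union over case-folded, whitespace-stripped
symbols, each gene carrying provenance flags (expression_serial,
expression_non_rescued, shrna_up, shrna_down); it is idempotent and
commutative, and an empty union is a warning, not an error.

Over-representation is the exact hypergeometric upper tail (scipy's exact
summation; cross-checked in tests against independent combinatorial
enumeration and the one-sided Fisher test), with the universe an explicit,
logged parameter — the default recommendation is the union of the
expression platform's genes and the shRNA library's genes, since external
enrichment services' backgrounds are not recoverable offline. BH
adjustment is the standard step-up, implemented in-package and
cross-checked against statsmodels. A `unique_assignment` mode counts each
query gene only toward its smallest containing pathway; an
include-interactors helper expands gene sets with first-degree neighbors
from a user-supplied interaction table. The bundled example gene sets are
synthetic stand-ins built from published pathway member lists, for
demonstrations and tests only.

The network builder takes the consolidated genes, the enriched pathways'
overlap genes, and optional extra genes as nodes; gene–gene edges are the
node-induced subgraph of the user's interaction table, and drug nodes
attach to their targets with FDA-approval flags and trial counts. The
summary reports the drug–target fraction of edges.

## Synthetic data: what it emulates, and what it does not

**Screen.** Libraries default to 18-nt barcodes (vendor length is not
published; configurable) generated uniformly at random and resampled until
pairwise Hamming distance ≥ 3 (checked by segment-bucket pigeonhole, so
full-scale generation stays fast). Counts are negative binomial via the
gamma–Poisson mixture around a common mean; treated means are multiplied by
planted ratios (defaults 4.0 enriched / 0.25 depleted) before resampling.
The default dispersion is 0.002, calibrated a priori so a planted 4-fold
clone at high coverage lands within ±25% of its ratio with ≥ 99%
probability (ratio CV ≈ √(2·dispersion)); dispersion 0 reduces to Poisson
for analytic checks. Default planted regime mirrors the published screen:
149 up + 78 down hit genes out of 5,500, depth near the published
~7×10⁶ total (10⁶ in the recovery tests for speed — stated in the tests).
Reads carry the barcode plus a constant 3' vector flank; a configurable
corrupt fraction (default 0.1) is split between random no-match sequences
and truncated short reads to exercise both QC filters, making the QC-pass
fraction an exact binomial proportion. Substitution errors are uniform;
no quality-dependent or indel error model.

**Time course.** One column per (condition, time point) for treated,
rescue and control over the nine-point grid {5, 10, 15, 30, 60, 180, 360,
600, 1440} min (rescue defaults to the same grid). Gene baselines are
N(8, 1) log₂ intensities with i.i.d. N(0, 0.05) noise. Planted serial
genes get a ±0.585 log₂ offset (1.5-fold — modest but comfortably past the
1.2 bound) over a 5-point window with random start; correlated genes get
monotone ramps; non-rescued genes are pinned to an exactly constant fold
change from the last treatment point through rescue (their planted SD is
literally 0, since any noise would exceed the 0.01 bound — the generator
states a world in which the rule's premise holds exactly). Batches are
assigned per time point (all conditions of a time point share a chip) with
fixed offsets (0, +0.25), so batch effects cancel in matched-time fold
changes but are visible to, and removable by, the batch-correction step.
Not emulated: probe chemistry, detection p-values, heteroskedastic
intensity-dependent noise, or biological replicates.

A green planted-recovery test therefore establishes that the selection
rules recover effects of the stated size under the stated noise — not
performance on real arrays or real screens.

## Numerical choices

- Ratios and bounds are compared strictly; boundary values never qualify.
- SDs use ddof 1 throughout (sample SD).
- BH adjustment caps at 1 and restores input order; ties are allowed.
- Loess span default 0.3; fold-change ratios always > 0 by construction.
- Barcode sizing errors name the smallest feasible barcode length
  (Singleton bound ⌈log₄ n⌉ + d − 1).
- All randomness flows through `numpy.random.default_rng(seed)`;
  regeneration with the same parameters is bit-identical, and TSV
  round-trips use round-trip float parsing.

## Known limitations

- The loess/VST/batch chain approximates, not reproduces, the
  bead-array-specific normalization stack; with real IDAT-derived data the
  upstream tooling should be preferred and the log₂ matrix handed over.
- Rank-based screen statistics (RSA/MAGeCK-style) are deliberately absent:
  the published selections are plain ratio thresholds, reproduced as such,
  and moderated-t differential expression is likewise out of scope.
- Enrichment here is a local ORA with an explicit universe; it stands in
  for, and does not reimplement, external services with proprietary
  statistics or versioned backgrounds.
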