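# Methods

## Readthrough-region model

A readthrough (TR) region is defined on the mature mRNA: starting at the
first base after the annotated stop codon, successive codons are read in
the annotated frame until the first TAA/TAG/TGA; the region excludes both
the annotated and the downstream stop. This exclusive convention makes the
arithmetic self-consistent for the AGO1 example (33 codons = 99 nt ending
at a TAG). If no downstream stop exists before the transcript end, the
region extends to the last complete codon and is reported with status
`no_downstream_stop`; such transcripts stay in the region table but are
excluded from score histograms. TGA is always treated as a stop —
selenoprotein-style recoding is not modeled.

Coordinates are 0-based half-open throughout; BED12 is the native
annotation format (GTF is converted on read, using exon and `stop_codon`
features). Splicing is exon-aware with a transcript→genome coordinate
bijection, so regions project correctly across junctions and strands.

Conservation scoring averages per-base track values (bedGraph natively;
bigWig accepted when pyBigWig is importable) over the region's genomic
footprint. Bases absent from the track are excluded from the mean rather
than imputed as zero, because imputation would bias means downward under
dropout; if coverage falls below `min_coverage` (default 0.8) the mean is
withheld (`low_coverage`). "Highly conserved" is a report-time threshold
(default 0.5) used only for flagging rows; no genome-wide fraction is
asserted from it, since that figure depends on the annotation release and
track used. Scanning is per-transcript; a gene-level rollup is left to the
caller.

## Alignment frame analysis

The codon frame is anchored to the reference row (human in the motivating
use): columns where the reference is gapped belong to no codon. A nonsense
codon is a reference-frame codon that is gap-free in a species and spells
a stop; partially gapped codons are skipped, not guessed, so alignment
artifacts are not miscalled as stops. Indels are maximal runs of
gap/non-gap disagreement with the reference; events separated by at least
one aligned column are distinct (no merging window). A species is
frame-intact iff it has zero nonsense codons and only length-multiple-of-3
indels. Translation renders gap-containing codons as `-` and stops as `*`.
Alignments are consumed as given; realignment is out of scope.

## dsRNA enrichment calling

Counts are normalized by median-of-ratios (geometric-mean reference over
genes nonzero in all samples). Fold changes are
`log2(mean normalized mutant + 0.5) − log2(mean normalized control + 0.5)`;
the pseudocount of 0.5 counts keeps all-zero genes at exactly zero fold
change. This deliberately simple estimator keeps the stage self-contained;
the residual rule is estimator-agnostic and accepts externally computed
fold-change tables.

The caller fits `lfc_dsrna ~ a + b·lfc_total` by OLS with intercept and
standardizes raw residuals by their sample SD (ddof = 1). The threshold is
|z| > 2.5; a leverage-adjusted (internally studentized) variant is
available behind a flag but is not the default, since with thousands of
genes leverages are negligible. A degenerate fit (zero residual SD)
produces no calls. Consistency across the two mutant comparisons is a
same-direction intersection. The Mann–Whitney U test on G/C proportions is
exact when both samples have ≤25 tie-free observations, otherwise the
tie-corrected normal approximation (scipy).

## Image quantification

Step 1 builds the nuclei projection mask: per-pixel maximum over z of the
DAPI channel, Otsu threshold (manual override available), morphological
opening (disk radius 2), connected components, size filter (default ≥500
projected pixels at the synthetic resolution), and removal of
border-touching nuclei (truncated cells would bias compartment means).
Per-slice nucleus voxels are above-threshold pixels inside the projection
footprint, inheriting the projected label. Step 2 masks the nucleolin
channel with the nuclei projection mask, repeats the procedure with a
nucleolus-scale size filter (default ≥20 px), and assigns each nucleolus
to the nucleus with maximal projected overlap (ties: larger overlap, then
lower label — deterministic). Step 3 averages the signal channel over
nucleolar voxels and over nucleus-minus-nucleoli (nucleoplasm) voxels per
cell; cells lacking a detected nucleolus or an empty compartment are
skipped with a warning. The ratio summary uses a paired two-tailed t-test;
zero-variance differences are reported as a degenerate p = 0 flag.

Foci counting max-projects the channel (maximum, not sum, to preserve
point contrast), removes background with a white top-hat (disk radius 5),
and detects local maxima with a minimum separation of 3 px — the
operational reading of "non-overlapping" — above a threshold of
mean + 5 SD of the top-hat image (a flat image yields zero foci). Maxima
are attributed to the cell footprint they fall in; counts are binned
0 / 1–5 / >5, with the lowest bin interpreted as exactly zero foci.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure each stage assumes, at
desk scale, with one seeded numpy Generator stream per output so outputs
are byte-identical across runs.

- **Transcriptome** (default 100 transcripts, 1–3 exons each, own
  chromosome, random strand): CDS ends in a canonical stop; TR regions are
  stop-free codon runs of 10–40 codons; 5% of transcripts carry TR bases
  scored in [0.8, 1.0] against a [0, 0.4] background; 2% deliberately lack
  a downstream stop; 2% of track bases are dropped. Truth stores planted
  ids and the exact mean of emitted TR scores. Real transcriptomes have
  overlapping isoforms, non-uniform conservation and incomplete
  annotations; passing tests show correctness of the scan and scoring
  logic, not robustness to annotation pathology.
- **MSA** (default 20 species × 33 codons, substitution rate 0.02): point
  substitutions are sampled so they never create a reference-frame stop;
  stops and indels appear only by explicit injection, making nonsense and
  indel truth exact. This mirrors a region under frame selection but means
  the null model is cleaner than a real alignment. The `tarsier_like`
  preset plants exactly one codon-aligned 3-nt deletion in the tarsier.
- **Counts** (default 2,000 genes × 2 assays × 3 conditions × 3
  replicates): gamma-Poisson draws with variance μ + μ²·disp
  (disp = 0.05), base means lognormal around 500 (floored at 50 so the
  fold-change noise is dispersion-dominated and residuals are close to
  homoscedastic); true total-RNA fold changes N(0, 0.5); dsRNA fold
  changes equal them except for 1% enriched (+2 log2) and 1% depleted (−2)
  genes, shared between mutants, with G/C drawn around 0.6 vs 0.4
  background. Library-size effects, batch effects and count outliers are
  not simulated.
- **Image stacks** (default 20 cells, 16×256×256 voxels): non-touching
  ellipsoidal nuclei on a jittered grid, 1–3 spherical nucleoli strictly
  inside each, piecewise-constant intensities (signal nucleoplasm 2000,
  nucleolus 2000 × factor, default factor 3.0 and n = 20 to match the
  observed nucleolar enrichment and sample size), additive Gaussian noise
  (SD 100, clipped, 16-bit; Poisson behind a flag). No PSF, no
  anisotropy, no touching nuclei — segmentation accuracy on these stacks
  is an upper bound on real-image performance.
- **Foci images** (default 3 foci per cell): Gaussian spots (σ 1.5,
  amplitude 8000) placed ≥6 px apart inside nuclei footprints with a 3-px
  edge margin; placement retries whole-cell configurations before
  declaring a density infeasible.

## Numerical conventions and edge cases

Ties in nucleolus assignment and label ordering are broken
deterministically. Histogram proportions are over status-ok regions only
and sum to 1. The residual caller requires ≥3 genes and a non-constant
predictor; `n_reps < 2` is rejected because a fold-change SD would be
undefined. Empty G/C test sets are skipped with a warning rather than an
error. Degenerate images (all background) segment to zero labels without
raising.

## Problem sizes

Defaults were chosen as the smallest sizes at which each stage's
statistical behavior is visible: 10,000 genes for null-calibration checks
(binomial error ~0.1%), 20 cells per stack, 1,000 random sequences for
oracle equivalence. The whole test suite and the acceptance script each
run in well under a minute on a laptop-class core.
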