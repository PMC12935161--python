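# Methods

This note records the models implemented in `isokit`, the choices made where
the design was open, and what the simulation-based validation does and does
not establish.

## Coordinate model

All in-memory coordinates are 0-based half-open; GTF files are read and
written in the on-disk 1-based inclusive convention, with conversion only at
the I/O boundary. Transcript coordinates are 0-based offsets along the
spliced exon chain in 5'→3' orientation, so on the minus strand the largest
exonic genomic coordinate maps to offset 0. `genome_to_transcript` /
`transcript_to_genome` are exact inverses on exonic positions, and
`project_interval` splits a transcript-space interval at exon junctions,
conserving length; both are verified against per-base brute-force lookup
tables in the test suite.

Intron compression for display is computed **per locus on the exon union
across isoforms**, not per isoform. Each maximal gap in the union is drawn as
exactly `intron_display_length` (default 100) display units and exonic bases
map with slope 1. The per-locus choice keeps every isoform of a gene on one
shared axis so shared exons and TSS guide lines align vertically; per-isoform
compression would misalign lanes whenever isoforms differ in intron content.

Transcripts whose CDS length is not a codon multiple are retained and flagged
`cds_incomplete` rather than rejected, since reference annotations contain
such records. Unknown GTF feature types and attributes survive parse→write
round trips verbatim; output ordering is deterministic (gene id, transcript
id, genomic start) so written files are byte-stable.

## ORF prediction and coding potential

External ORF predictors are deliberately not wrapped; their functional roles
are implemented internally so the pipeline is self-contained and testable at
the desk:

- **Candidate generation.** Every ATG-initiated reading frame per frame,
  extended to the first in-frame stop (or transcript end, flagged
  3'-incomplete), one candidate per (frame, stop) anchored at the 5'-most
  start, minimum length 75 nt (configurable). Verified by exact set equality
  against an independent ATG-anchored scanner on random sequences.
- **Features.** ORF length (log), ORF coverage of the transcript, the Fickett
  (1982) TESTCODE statistic computed through the published position/content
  probability and weight tables (shipped as data in `orf.py`), and the mean
  in-frame hexamer log-odds log(f_coding/f_noncoding) from a pseudocounted
  table trained on user-supplied coding (in-frame, step 3) and noncoding
  (all-frame, step 1) sequences. Hexamers containing N are skipped; start and
  stop matching is exact.
- **Combiner.** Unpenalized logistic regression over the four features;
  perfect training separation (where the MLE does not exist) triggers a
  flagged ridge (L2, C=1) refit. The best candidate by predicted probability
  is selected, ties broken by longer length then 5'-most start, and discarded
  below probability 0.5 (configurable). The CLI trains on the input GTF's own
  annotated CDS versus codon-shuffled copies; library users can supply any
  labelled sets.

The stop codon is excluded from written CDS records; predicted transcripts
carry `orf_source "predicted"` and, when no stop was found, `cds_incomplete`.

Two derived attributes feed the figures: **uORF presence** (an ATG-initiated
ORF of ≥ 9 nt with an in-frame stop lying fully within the 5' UTR — upstream
ORFs overlapping the main CDS are out of scope) and **NMD prediction** by the
literature-standard 50-nt rule (stop codon more than 50 nt upstream of the
last exon–exon junction; single-exon transcripts are never flagged). Where an
annotation already carries an NMD biotype, that attribute takes precedence in
display.

## Differential expression

The DE stage is a simplified, documented re-implementation of the standard
count-based methodology, validated by simulation rather than bitwise
agreement with any external tool:

- **TMM.** Reference sample = upper-quartile rule; per sample the factor is
  the inverse-asymptotic-variance weighted mean of gene-wise log2 ratios M
  after trimming 30% per tail by M and 5% per tail by average abundance A
  (rank-based, average ranks at ties); genes with a zero in either sample are
  excluded; factors are rescaled to geometric mean 1. The acceptance script
  checks agreement to 1e-8 with an independently coded direct implementation.
- **Dispersion.** Per-transcript NB dispersion maximizes the Cox–Reid
  adjusted profile likelihood (group means profiled out by Newton iteration;
  adjustment −½ log det of the Fisher information) on a fixed grid of 41
  log-spaced points in [0.001, 5], then log-dispersions are shrunk with
  weight 0.5 toward the mean of their abundance bin (20 quantile bins).
  All-zero transcripts are excluded and reported. The grid and weights are
  stated because results must be deterministic.
- **Test.** NB GLM with offsets log(library × TMM factor); full model has one
  mean per group, null a shared mean. The F numerator is the deviance drop;
  the denominator is the deviance dispersion (residual df = n−2) moderated by
  empirical-Bayes squeezing (moment matching of log variances to a scaled F
  prior, trigamma-inverse Newton solve); p-values come from F(1, d0+df) and
  are BH-adjusted. log2FC is the case-minus-control coefficient in log2
  units, with control = the first group in the design file unless overridden.
- **Filtering.** Transcripts with CPM > 1 in fewer than min(group size)
  samples are removed before dispersion estimation and reported separately; a
  filter of this kind is needed for stable dispersion fits at the low end.
- **Significance** is declared at adjusted p < 0.05 by default (configurable).

Under the simulated null (NB dispersion 0.1, 5 vs 5 samples, ~2000
transcripts) the raw p-value distribution is close to uniform (fraction
below 0.05 within 0.05 ± 0.02, KS < 0.05), label swap exactly negates log2FC,
and power at |log2FC| = 2 with 10 vs 10 samples exceeds 0.95. Only unpaired
two-group designs are supported; covariates and paired designs are out of
scope.

## Differential isoform usage

Counts over the k ≥ 2 expressed isoforms of a gene are Dirichlet-multinomial:
proportions π on the simplex, precision s > 0. Fits maximize the exact DM
log-likelihood by bounded quasi-Newton (L-BFGS-B, tolerance 1e-8) on
logit-transformed proportions and log precision from a fixed deterministic
start (pooled proportions, precision 10); gradients are analytic. Samples
with zero gene total are dropped per gene, not imputed. As s → ∞ the DM
log-likelihood approaches the multinomial one (checked numerically).

- **Gene test.** LRT of group-specific proportions (precision shared under
  both hypotheses) against shared proportions; χ² with k−1 df. Per-group
  precision is out of scope.
- **Transcript test.** The gene is collapsed to "this isoform vs the rest"
  (beta-binomial) and the same LRT run with 1 df — the simplest symmetric
  construction; for k = 2 both transcripts get the same p-value by design.
- **Stage-wise correction.** BH screening across gene p-values at α;
  within screened genes, Holm–Šidák adjustment of transcript p-values tested
  at α·(n screened)/(n genes). Reported transcript adjusted p-values are
  rescaled to the overall α scale so `confirmed ⟺ tx_p_adjusted ≤ α`;
  transcripts of unscreened genes are never confirmed.
- **Effect size.** Δusage = difference of group means of per-sample usage
  proportions (case − control), displayed as signed percentage points with
  one decimal; per gene the Δusage values sum to zero. A ratio definition
  was considered and rejected as less stable for low-usage isoforms.
- **Gene filter.** Genes with fewer than 10 total reads in more than half the
  samples, or fewer than two expressed isoforms, are excluded and reported.

Simulations at the package's study conditions (precision 50, depth 300, 10
vs 10 samples) put the gene-level type-I error within 0.05 ± 0.03, recover DM
proportions within 0.05 at 40 samples of depth 200, and hold the realized
overall FDR of the two-stage procedure at or below 0.08 across 20 replicate
mixtures with 10% true usage-shift genes, with the gatekeeping invariant
(confirmed ⇒ screened) never violated.

## Visualization

All panels build a structured drawing model — rectangles, lines and text with
semantic roles and metadata — which the tests read back directly: exon box
widths equal display lengths, introns occupy exactly 100 display units, box
plot medians equal numpy medians of the plotted rows, usage bars sum to 1 per
group. The native SVG writer is deterministic (fixed float formatting, no
timestamps or generated ids), so identical inputs give byte-identical files;
a golden SVG of the documented toy locus is kept under `tests/data/`. PNG and
PDF output render the same drawing model through matplotlib. Lane order is
annotated isoforms before predicted ones, then by transcript id, unless an
explicit order is given. Expression box plots use log2 CPM (prior 0.5),
labelled as such; continuous non-positional features are max-normalized per
column for bar scaling.

## Synthetic data

The generator emulates a long-read isoform study at desk scale. Each gene has
a core block of coding exons flanked by two alternative first and two
alternative last exons; isoforms pick one of each, so they share the planted
ORF but differ in TSS and UTRs. Coding sequence uses a biased codon
distribution (one preferred codon per amino-acid family, weight 4:1), which
gives real-CDS-like hexamer periodicity against uniform-random background;
25% of genes are noncoding and 20% of coding transcripts are emitted without
CDS records (the "novel" set used to evaluate frame recovery). Counts arise
as lognormal gene means (σ = 1), mild lognormal library factors (σ = 0.1),
NB gene totals (dispersion 0.1) and DM allocation to isoforms (precision 50)
— defaults chosen as typical of bulk long-read cDNA experiments. Planted
effects: usage-shift genes move 0.3 of usage from their major to their minor
isoform in the case group; DE transcripts (planted only in non-shift genes so
each effect is cleanly attributable) scale their case proportion by 2^±2 with
the gene total rescaled so other isoforms keep their expectation. Everything
is bit-reproducible from (config, seed).

What the simulations do **not** capture: positional sequencing biases and
read-level error of real long reads, correlated library composition effects,
paired tumor/normal designs, annotation errors, and genuine hexamer
statistics of real genomes. Passing tests therefore demonstrate correctness
of the implemented statistics under their own model assumptions and
calibrated behaviour under DM/NB data — not performance claims on any
particular biological dataset.

For statistical experiments that do not need genomic sequence, the
light-weight `toy_models` helper provides minimal single-exon gene models so
count simulations scale to thousands of transcripts in seconds; problem sizes
used in the test and acceptance runs (for example 2000 transcripts for DE
calibration, 500 null genes and 20 × 100-gene mixtures for DIU) were chosen
as the smallest sizes at which the Monte Carlo noise is well inside the
asserted tolerances.

## Numerical details and edge cases

- Newton fits of NB group means clip steps to ±5 on the log scale and stop at
  1e-10; deviance terms use the y log(y/μ) = 0 convention at y = 0.
- The trigamma-inverse solve follows the standard Newton recursion with
  asymptotic guards; prior df is capped at 1e6 (effectively χ²).
- DM optimization bounds: logits in ±30, log precision in [log 1e-3,
  log 1e7]; LRT statistics are floored at 0.
- BH adjustment delegates to `statsmodels.stats.multitest`; the brute-force
  definition serves as the test oracle.
- p-values are clipped away from exact 0 to keep downstream logs finite.
- Degenerate inputs: all-zero samples are an error for TMM; all-zero
  transcripts are excluded and reported; single-isoform genes are skipped in
  DIU with a reason code; empty model lists write a header-only GTF.

## Known limitations

Unpaired two-group designs only; no gene-level aggregation test; no
covariates or usage QTLs; uORFs overlapping the main CDS are not detected;
no selenocysteine/readthrough or non-ATG starts; GFF3 is not supported (GTF,
GENCODE attribute dialect only); the feature-table contract replaces direct
wrappers of external domain/signal predictors — their outputs are consumed as
TSV rows.
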