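# Methods

This note records the models, parameter choices and numerical conventions
behind `secanalyze`, and what the synthetic benchmark does and does not
establish about real data.

## Coordinate and format conventions

All coordinates are 0-based half-open (BED convention); GFF3 is converted
at the parsing boundary. Chromosome names are matched as exact strings —
no "chr" aliasing — because silent aliasing hides real input mismatches.
Strand is carried but ignored by interval algebra: H3K27Ac enrichment
domains are unstranded. Stitching treats the gap between sorted intervals
as `next.start − prev.end` and merges when the gap is ≤ the threshold
(inclusive: "within 12.5 kb" is read as ≤ 12.5 kb), so a threshold of 0
reduces to the classic overlapping/book-ended merge.

## Super-enhancer identification

The chain is promoter exclusion → stitching → quantification → inflection
cutoff → gene assignment.

*Promoter exclusion* removes peaks **fully contained** within
±`promoter_flank` (default 2500 bp) of any TSS; a peak that merely touches
the flank is retained intact. This is the literal reading of "a region not
contained within" the promoter flank; an any-overlap variant would also be
defensible but removes real distal signal attached to promoter-proximal
peaks.

*Quantification* sums per-bp read depth of the treatment track over the
stitched region, scales to reads per million mapped reads (rpm), subtracts
the same quantity from the input track, and floors at zero **per region**
(not per bp). Per-region flooring matches the notion of a total
background-subtracted signal; per-bp flooring would bias signals upward in
noisy regions. Base pairs outside track coverage contribute zero. The
subtraction is applied after stitching, over stitched regions.

*Inflection cutoff.* Enhancers are sorted by ascending signal; ranks are
scaled to x ∈ [0, 1] and signals min-max scaled to y ∈ [0, 1]. The cutoff
is the discrete argmax of x − y, which for a convex rank curve is exactly
the point where a line of slope 1 is tangent to the curve — the standard
geometric construction for hockey-stick curves. Ties break toward the
larger rank (fewer SEs): the conservative direction. Min-max scaling makes
the call invariant to multiplying all signals by a positive constant. Two
degenerate cases yield zero SEs and a `degenerate` flag: all signals
identical, and curves indistinguishable from the diagonal
(max(x − y) ≤ 1e-12, e.g. perfectly linear signals). Fewer than three
regions cannot support a cutoff; the pipeline then reports everything as
typical with the flag set. One discrete-geometry caveat: appending an
enhancer below the current minimum rescales both axes and can, in
principle, shift the argmax; empirically (100 random landscapes per run of
the test suite) no existing SE call is lost.

*Gene assignment* takes transcriptionally active genes whose TSS lies
within `assign_window` (default 50 kb) of an SE **edge** (not its center;
edge measurement is the natural reading of a window around a region).
Activity is an input flag on the annotation, not computed here — the
expression threshold that defines "active" belongs to the upstream
expression analysis, so the flag travels on the GFF3 `active` attribute.

## Occupancy, dependent peaks, nomination

Peak-to-gene annotation uses any overlap of a peak with the ±50 kb TSS
window, deliberately symmetric with the SE assignment rule. Dependence
defaults to `min_overlap = 1` bp — the strictest definition of loss; the
parameter is exposed for robustness analyses. The dependent-peak search is
a per-chromosome vectorized overlap scan: a prefix-max index trick is only
sufficient for 1-bp overlap, whereas the scan is correct for arbitrary
`min_overlap` and fast at the scales involved. Nomination is pure set
algebra over gene-id strings, matched case-sensitively; cardinalities of
all parent sets and pairwise intersections are reported and checked for
inclusion consistency after every pipeline run.

## Marker and DEG criterion

Counts are library-size normalized to 10,000 per cell and log1p
transformed; an all-zero cell keeps size factor 1 (with a warning). Fold
change is computed on de-logged group means with pseudocount 1 in
numerator and denominator — the standard marker-fold convention, finite
for all-zero genes. The test is a two-sided Wilcoxon rank-sum
(tie-corrected normal approximation) on normalized values; p-values are
raw by design, with an optional Benjamini–Hochberg column in the output
table. For cluster markers the expressing-fraction gate (> 25%) applies to
the target cluster only. For condition DEGs inside a cluster the gate uses
the larger of the two group fractions: a strongly down-regulated gene is,
by construction, poorly detected in the knockout cells, and the symmetric
gate additionally makes the result exactly antisymmetric under swapping
the condition labels (up and down lists exchange; folds invert exactly,
because the fold is a ratio of the same two pseudocounted means).

Observed behavior under the defaults (checked by the test suite on
negative-binomial nulls, 1000 genes, 200 vs 800 cells, three seeds): the
fraction of null genes at p < 0.01 is ≈ 0.9–1.5%, i.e. the asymptotic
rank-sum test is approximately calibrated at this sample size despite
heavy ties; planted 4-fold markers are recovered essentially completely.

## 3C-qPCR

Input is post-qPCR template quantities from equal-input libraries, not raw
Ct. Within each (condition, replicate) the short-range ligation control
quantity divides every fragment quantity (×100), which cancels replicate-
and sample-level efficiency differences; the control is therefore exactly
100% in every replicate, and the profile of a replicate is invariant to
rescaling its quantities. Summaries are mean ± sd (ddof 1) across
replicates. Condition comparison reports the ratio of mean interaction
frequencies and a plain two-sided t-test per fragment; with fewer than
three replicates only the ratio is reported, and zero variance in both
groups is flagged as degenerate rather than assigned a p-value.

## Synthetic data

The generator defines the benchmark conditions; its defaults are fixed and
documented here rather than tuned per run.

*Enhancer landscape* (one 10 Mb synthetic chromosome `chrS`, 50 bp bins):
20 SE loci of 3–8 constituent peaks (widths 800–2000 bp, intra-locus gaps
500–8000 bp, always below the stitch threshold) among 400 single-peak
typical enhancers (600–1500 bp). Entities are separated by more than the
stitch gap plus 2 kb so each planted entity stitches to exactly one
region. Constituent coverage is Poisson with per-bp mean
`signal_ratio × typical_depth` (defaults 20 × 2.0) over a flat Poisson
background (0.25), with a flat Poisson input track; library sizes are the
realized read totals. Each SE locus receives a designated active target
gene 3–40 kb past its edge; 30 decoy peaks are planted fully inside
promoter flanks of non-target genes to exercise the exclusion step.
Per-bp Poisson aggregated to 50 bp bins keeps files at desk scale while
preserving the rpm arithmetic exactly.

*Counts*: negative-binomial with variance μ + 0.5 μ², per-gene base means
log-normal(−1, 1), three clusters × two conditions (800 cells total in the
preset). Planted effects multiply the mean in the target (cluster,
condition) cells. In the preset the planted up- and down-DEG base means
are chosen so the per-cell library-size shifts cancel (an up gene with
base m and fold f adds m(f−1); a down gene with base m·f removes the
same), because an unbalanced planting would otherwise leak composition-
bias false DEGs through the library normalization. Planted DEG/marker
genes override their base mean (2–8) so the planted fold is detectable at
the preset cell numbers.

*Nomination ground truth* is constructed geometrically, independent of the
code under test: down-DEG decoys are drawn only from genes farther than
the assignment window + 5 kb from every planted SE locus, so the expected
triple intersection is exactly the one designated target gene.

*3C*: multiplicative log-normal noise with CV 0.1 (σ² = ln(1 + cv²), mean
1), four replicates, a short-range control at true IF 100, and a planted
3× induction at the promoter-proximal enhancer fragments.

What the synthetic benchmark does **not** model: mappability and GC bias,
fragment-length effects, peak-caller boundary noise, doublets and ambient
RNA, batch effects, or restriction-site geometry. Passing the suite
demonstrates algorithmic correctness against oracles and planted truth at
desk scale, not end-to-end fidelity on sequencing runs; real-data counts
(numbers of enhancers, SEs, occupied genes, DEGs) depend on upstream peak
calling and pipeline versions and are expected to differ.

## Problem sizes and determinism

The test suite and the acceptance script run the study at the preset sizes
above (420 enhancer entities, 800 cells × 300 genes, 200-peak dependence
sets, 4-replicate 3C tables), which the package treats as its reference
desk-scale configuration. Every stochastic component takes an explicit
integer seed; generators are bit-reproducible given (parameters, seed),
pipeline reruns produce byte-identical outputs, and the orchestration
report contains no timestamps.
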