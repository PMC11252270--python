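# secanalyze

Regulatory-genomics target nomination for lineage-commitment studies:
super-enhancer calling from H3K27Ac ChIP-seq, proximity-based peak-to-gene
assignment, knockout-dependent peak loss, cluster-restricted single-cell
differential expression, set-intersection target nomination, and 3C-qPCR
interaction-frequency normalization — with a synthetic-data generator that
plants ground truth for every stage.

The package is aimed at analysts reproducing the classic "which gene does
this chromatin regulator drive through a super-enhancer?" inference, as used
for example to nominate the osteoclast master transcription factor *Nfatc1*
as a super-enhancer-driven target of the chromatin remodeler ARID1A during
osteoclastogenesis. All stages run on plain-text inputs (narrowPeak/BED,
bedGraph, GFF3, MatrixMarket, TSV) at desk scale.

## The methods

**Super-enhancer (SE) calling.** H3K27Ac peaks fully contained within
±2.5 kb of a TSS are discarded; surviving peaks within 12.5 kb of one
another are stitched into candidate enhancers. Each stitched region *r* is
quantified as background-subtracted occupancy in reads per million,

    S(r) = max(0, Σ_bp chip(bp)/N_chip·10⁶ − Σ_bp input(bp)/N_input·10⁶),

ranked ascending, and both axes min-max scaled to [0, 1]. The cutoff is the
geometrically defined inflection of the hockey-stick curve — the discrete
point maximizing x − y, i.e. where a slope-1 tangent touches the scaled
rank curve; enhancers above it are SEs. Transcriptionally active genes with
a TSS within 50 kb of an SE edge are assigned to it.

**Occupancy and dependent peaks.** A factor occupies a gene when any of its
peaks overlaps the ±50 kb TSS window. A binding site is *dependent* on a
condition when no peak in the comparison condition overlaps it (≥ 1 bp by
default).

**Marker / DEG criterion.** A gene is a cluster marker when it is ≥
1.28-fold overexpressed (ratio of de-logged mean normalized expression),
detected in > 25% of the target cluster's cells, and its two-sided Wilcoxon
rank-sum p-value is < 0.01 (raw, by design). The same machinery restricted
to one cluster with groups defined by condition yields control-vs-knockout
DEG lists.

**Nomination.** Candidate direct targets are the triple intersection of
SE-associated genes, factor-occupied genes and direction-filtered DEGs
(optionally restricted to a curated lineage gene set).

**3C-qPCR.** Within each replicate, fragment quantities are divided by the
short-range ligation control and scaled to percent; conditions are compared
per fragment by the ratio of mean interaction frequencies with a two-sided
t-test.

## Worked example

```sh
secanalyze run --preset ocfate --out run_out --seed 1
```

simulates the full synthetic study (20 planted SE loci among 400 typical
enhancers at 20:1 signal contrast, an occupancy peak set, a wild-type /
knockout peak pair with 40 planted losses, a 300-gene × 800-cell count
matrix with planted DEGs, and a 3C table) and runs every stage. It prints

```json
{"n_enhancers": 420, "n_super": 20, "nominated": ["G0288"]}
```

meaning all 420 planted enhancer entities were recovered after promoter
exclusion and stitching, the inflection cutoff separated exactly the 20
planted SE loci from the 400 typical enhancers, and the set intersection
nominated the single planted target gene (SE-associated, occupied, and
down-regulated in the knockout within the decision cluster). The output
tree contains `report.json` with all cardinalities — in this run 61
SE-associated genes, 170 occupied genes, 40 dependent peaks, 10 up / 12
down DEGs, and a 3C induction ratio of 2.84 at the planted 3× enhancer
fragment (E2) — plus per-stage TSV/BED outputs and a rank-vs-signal
hockey-stick plot. The same analysis runs on user data via
`secanalyze run --config run.yaml` or the per-stage subcommands
(`call-se`, `occupancy`, `dependent-peaks`, `markers`, `deg`, `nominate`,
`three-c`).

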