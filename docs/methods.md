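# Methods

## Coordinate model

All intervals are 0-based half-open (BED convention) internally; two
intervals share a base iff `a.start < b.end and b.start < a.end`. Sorting is
lexicographic by chromosome, then start, then end, with stable ties. Peak
subtraction removes whole intervals rather than trimming, because the unit of
analysis is the peak, not the base pair: a peak contaminated by control
signal anywhere is discarded. The default overlap criterion for every set
operation is ≥ 1 bp and is configurable (`min_overlap_bp`); no evidence-based
bp threshold is imposed.

## Replicate consensus

Each replicate is filtered at a strict FDR cutoff (`score < fdr_max`; 0.05
for factor ChIP, 0.2 for H3K9 acetylation, reflecting the different score
calibrations of the two assay types). Surviving peaks from all replicates are
pooled and fused into maximal candidate regions; a candidate is retained when
peaks from at least `min_support` distinct replicates overlap it (default 2
of 3). Consensus regions are reported as the merged union rather than any
single replicate's coordinates: unions are reproducible, conservative
(contain every contributing peak), and independent of replicate ordering.
"Present in a replicate" means ≥ 1 bp overlap with the candidate region.

Under independent replicate detection at reproducibility *r*, a true peak
survives 2-of-3 consensus with probability `r³ + 3r²(1−r)`; the acceptance
suite checks the observed survival of 1,000 planted peaks against the exact
99% binomial interval around this value. Dense peak sets inflate survival
slightly (neighbouring true peaks merge into one candidate and pool their
support), so the calibration experiment uses a 15 Mb genome where the
collision rate is a fraction of a percent.

## Promoters, nearest TSS, and location classes

Promoters are 2 kb upstream through 0.5 kb downstream of the TSS,
strand-aware: `[TSS−2000, TSS+500)` on +, `[TSS−499, TSS+2001)` on −, both
2,500 bp, clipped at chromosome bounds. The TSS of a − strand gene is
`end − 1` (the biological 5′ end); genes with multiple isoform records use
the 5′-most TSS, and exon structure is taken from that 5′-most isoform.

Peaks are anchored at their midpoint `floor((start+end)/2)` for both distance
computation and location classification — summit coordinates are unavailable
in BED inputs, and the midpoint is the only anchor defined for every dialect.
Nearest-TSS assignment minimizes |midpoint − TSS| over all genes on the
peak's chromosome, strand-ignored; ties break to the smaller TSS coordinate,
then lexicographic gene id, making assignments fully deterministic. Peaks on
chromosomes without genes receive a null assignment with a warning rather
than an error, so partial annotations degrade gracefully.

Location classification assigns a single class per peak by midpoint
membership with priority promoter > 5′UTR > 3′UTR > exon > intron >
intergenic, so class counts always partition the peak set. UTRs are exonic
sequence outside the thick (CDS) interval of the BED12 record.

## Feature enrichment

```
enrichment = (n_feature / n_peak) / (N_feature / N_background),
N_background = floor(genome_length / avg_feature_length)
```

`n_feature` counts peaks overlapping ≥ 1 feature interval. Canonical average
feature lengths are 601 bp (CpG island), 2,500 bp (promoter), and 271 bp
(enhancer); unknown classes fall back to the empirical mean feature length.
`genome_length` is the sum of the supplied chromosome sizes — not a fixed
mouse-genome constant — so the statistic transfers unchanged to synthetic
genomes. `N_background` uses floor division.

The windowed background model treats a peak as a point falling into
feature-sized windows. For peaks of width *w* against features of average
length *L*, any-overlap counting inflates the null expectation by roughly
`w/L`; the null-calibration experiment therefore uses 50 bp peaks against
2.5 kb features (inflation 2%), and wide-peak enrichments should be read with
this in mind.

## Expression

RPKM is `counts / (gene_length_kb × library_size_millions)`, with gene length
the exon-length sum of the 5′-most isoform. z-scores are computed per gene
across samples as `(x − mean) / sd` with the sample (n−1) standard deviation
and no prior log transform (a `log2` option exists but is off by default;
the choice between z-scoring RPKM and log-RPKM is a genuinely open design
point, and raw RPKM is the default because it requires no pseudocount).
Constant rows z-score to all zeros with a logged warning rather than NaNs.

Tissue-enrichment calls use `fold = (mean_A + ε)/(mean_B + ε)` with
pseudocount ε = 0.1 RPKM (avoids division by zero while perturbing
moderately expressed genes by < 1%); thresholds are inclusive ("at least
two-fold"). Hierarchical ordering is agglomerative clustering of z-score rows
(Euclidean distance, average linkage), deterministic given input order.

## Motif scanning and enrichment

PWM columns are renormalized after adding a 0.01 pseudocount; scores are
`Σ log2(p_col(base)/bg(base))` against a uniform background, both strands; N
bases contribute 0 bits. A window is a hit when its score reaches
`score_fraction × max attainable score` (default 0.8) — a relative threshold
is used because no absolute cutoff is published for this analysis and it
adapts to motifs of different information content.

Enrichment is sequence-level (zero/one occurrence): population = targets ∪
backgrounds, successes = sequences with ≥ 1 hit, draws = targets, and the
p-value is the hypergeometric upper tail; q-values are Benjamini–Hochberg
across the motif library. Background sequences are length-matched regions
sampled uniformly away from all peaks with a caller-supplied seed — a
documented substitute for the unstated background of external motif tools.

## Overlap statistics

The Yates-corrected chi-square uses the 2×2 shortcut form with the continuity
term floored at zero (`max(|ad−bc| − N/2, 0)`), df = 1; a zero margin raises
rather than returning 0/0. The test suite cross-checks it against an
independent expected-counts implementation to 1e-9 on 1,000 random tables.
The gene universe of an overlap test is a mandatory argument — results
depend on it strongly, so it is never defaulted silently. Reported p-values
floor at 2.2e-16 (`"< 2.2e-16"`).

## GRN construction

Edges are binary regulatory-potential links (binding-derived), not signed
activation/repression: the evidence is chromatin association, which cannot
distinguish direction of effect. Default target filters admit genes that
encode transcription factors and show embryonic-CNS-enriched expression; both
filters are configurable. Co-binding enters as an edge attribute (the target
gene is nearest to an intersecting peak of two factors), acetylation
dependence as a node attribute. Externally published factor target sets can
be imported as gene lists with provenance `"imported"`. Candidate targets
without an expression label are skipped with a warning. Exports (edge TSV,
GraphML, DOT) use sorted orderings so outputs are byte-stable; the edge TSV
round-trips back to an identical edge set.

## Synthetic data

The generator emulates the study design, not sequence realism. Defaults: a
3 × 1 Mb genome with 300 non-overlapping multi-exon genes, 150 CpG islands
(half placed at promoters), 200 enhancers; 300 true peaks per condition
(width ~N(400, 100²) bp, min 50) with 40% planted into promoters; three
replicates at 80% reproducibility with ±10% coordinate jitter; true-peak FDR
~ Uniform(0, threshold/2) and noise-peak FDR ~ Uniform(0, 1), which makes
threshold filtering meaningful without modelling read-level statistics;
controls at 10% of the peak count with 5% coinciding with true peaks; a
co-bound factor sharing 20% of peaks; negative-binomial counts (dispersion
0.05) over four tissue groups of three samples with a 4-fold expression
multiplier planted into 20% of genes in embryonic-CNS samples; and a GC-rich
8-bp consensus site planted into 50% of target sequences. Reproducibility
0.8 and three replicates reflect a typical replicated ChIP design; the
4-fold planted expression effect makes the two-fold classification threshold
a non-trivial but recoverable target under NB noise.

All generators derive independent child RNG streams from `(master seed,
stream index)`, so any stage can be regenerated alone and whole runs are
byte-identical under a fixed seed. Independently placed peaks of a second
factor are rejected away from the first factor's intervals, so measured
co-binding reflects only the planted fraction.

What the generator does **not** emulate: read-level sampling (peaks are
intervals, not pileups), fragment-length effects, sequence composition (the
genome is i.i.d. uniform ACGT, so CpG islands have no elevated CpG content),
correlated replicate noise, and isoform-level expression. Passing recovery
tests therefore demonstrates correctness of the set algebra, statistics, and
classification logic under the stated noise model — not robustness to
artefacts of real chromatin data.

## Problem sizes and numerical choices

Calibration experiments use 1,000 planted peaks (binomial-interval checks),
5,000 peaks (promoter-enrichment closed form), 10,000 peaks (enrichment
null), 200 null motif libraries (type-I control), and 600 genes / 200
planted genes (expression recovery) — sizes at which the 99% binomial and
3-SE Monte-Carlo bands are tight enough to detect real defects while keeping
the whole suite interactive. Scan-score comparisons use a 1e-12 slack so
ties at the threshold count as hits on both code paths; chi-square
cross-checks demand 1e-9 agreement; z-score standardization is checked to
1e-9.

## Known limitations

- Consensus support counts can pool across distinct true peaks that merge
  into one candidate region in dense peak sets.
- The feature-enrichment null is exact only for point-like peaks (see above).
- Whole-interval control subtraction is conservative: a single contaminated
  base removes the entire peak.
- The hypergeometric motif test ignores sequence length differences between
  targets and background beyond the length matching of the sampler.
- GRN edges are undirectional in effect (no activation/repression sign) and
  unweighted; cooperative regulation appears only as a co-binding flag.
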