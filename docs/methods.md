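# Methods

This note documents the models, rules and numerical choices behind
`exosmallrna`, and what the synthetic data used by the test-suite does
and does not establish about real libraries.

## Read processing

Adapter trimming removes the best 3′ occurrence of the adapter prefix: a
candidate cut at read position *i* aligns `min(len(adapter), len(read)−i)`
bases, needs at least `min_overlap = 12` aligned bases and a mismatch
fraction ≤ `max_error_rate = 0.25`, and everything from the cut onward
(including read-through past a fully contained adapter) is removed. Among
acceptable candidates the one with the most matching bases wins, ties
going to the longer overlap and then the leftmost position. This
tie-break is our own commitment — trimmers differ in how they rank
equally scored occurrences — and is pinned by a brute-force scorer in the
tests. Reads that trim to nothing are flagged and excluded, and counted
in the trimming report.

Alignment is consumed, not performed: inputs are SAM/BAM with up to 50
placements per read. Scores come from the `AS` tag (fallback: −NM with a
warning); per read only equal-best-score alignments are kept, at most 50,
in deterministic (chrom, start) order.

## Featuretype assignment

Annotations: GENCODE-style small genes are kept when their spliced
(summed-exon) length is ≤ 120 nt — "total length" is read as spliced
length, the conventional meaning for transcripts; for the mostly
single-exon small genes the distinction rarely matters — and when their
gene type is not `sense_intronic`, `sense_overlapping` or `miRNA` (miRNAs
come from the miRBase-style source, precursor and mature records
separately). tRNA genes carry anticodon/amino-acid metadata; piRNA
intervals are merged transitively on ≥ 1-base same-strand overlap (no
distance threshold); repeat copies stay separate records sharing a
family so they can induce multi-mapping. Overlap queries are same-strand
by default with a strand-agnostic switch, since small-RNA library
protocols are stranded.

The cascade, applied to the union of featuretypes overlapped by a read's
best alignments, in order: (0) empty → `Unannotated` (our extension so
the function is total; such reads are excluded from class-fraction
denominators by default, with a flag to include them); (1) singleton →
assign; (2) length > 25 nt eliminates mature miRNA, otherwise the
precursor is eliminated; (3) length > 32 nt eliminates piRNA; (4)
singleton → assign; (5) exactly two candidates, one a repeat → assign the
non-repeat; (6) with ≥ 2 alignments, drop featuretypes supported by only
one alignment (support = number of alignments whose overlap set contains
the featuretype); (7) singleton → assign; (8) otherwise `Ambiguous`. The
repeat-preference rule is not re-applied after step 6. GENCODE subtypes
(snoRNA, rRNA, snRNA, miscRNA …) are distinct classes throughout the
cascade, so composition reporting keeps them apart; a read over a snoRNA
and an rRNA is not a singleton union. Resolved calls are refined to the
miRNA name, `tRNA-<aa>-<anticodon>`, repeat family or gene type;
disagreeing supporters yield a `multi:` label counted separately.

An independent brute-force interpreter of the same prose rules is kept in
the test-suite and checked exhaustively over featuretype unions (≤ 4
types) × read lengths 15–90 × alignment-support patterns.

## Quantification

Class fractions are read-weighted; unique-sequence tables (identical
trimmed sequences collapsed) are emitted alongside per-read tables for
callers who want sequence-weighted summaries. `Ambiguous` is a reported
class. rpm columns sum to 10⁶.
Length histograms cover the 15–90-nt library window. Gene coverage is
counted 5′→3′ in gene orientation; a read whose call is supported by *n*
genes contributes 1/*n* per gene so total signal is conserved — the
apportionment is our choice, as nothing in the underlying design fixes
it. Top-*k* shares are computed on rpm with deterministic label-order
tie-breaking.

## Statistics

* **Filtering**: keep a feature with ≥ 15 reads summed over cell samples
  OR ≥ 5 over exosome samples.
* **TMM**: reference column = the one whose 75th percentile of
  library-scaled counts is closest to the mean of those percentiles;
  log-ratios M and abundances A on doubly positive features; rank-trim
  30 % on M and 5 % on A; precision (delta-method) weights
  (N−y)/(N·y) summed over the pair; factors rescaled to geometric mean 1.
  Agreement with the reference implementation of the published algorithm
  (edgeR `calcNormFactors`) is asserted within 2 % in the tests.
* **Imputation**: zero counts are replaced, per sample, by half the
  minimum nonzero normalized value — an estimate of the lower limit of
  detection — before taking logs. Natural log internally; fold-changes
  are reported in log2.
* **Clustering**: genes by euclidean distance on per-gene z-scored
  values, samples by 1 − Pearson r, average linkage; rows/columns are
  label-sorted first so equal-distance merges are deterministic. Newick
  export for both dendrograms.
* **Common dispersion**: library sizes (optionally TMM-scaled) are
  equalized to their geometric mean by linear scaling of counts; the
  shared NB dispersion φ maximizes the conditional log-likelihood
  Σ_g Σ_groups [Σ_i ln Γ(y_i + 1/φ) − n ln Γ(1/φ) + ln Γ(n/φ) −
  ln Γ(z + n/φ)] on a 41-point log-spaced grid refined by bounded scalar
  minimization (tolerance 1e-6). This linear equalization approximates
  the quantile adjustment used by the edgeR reference; at the near-equal
  library sizes of the designs here the difference is negligible
  (parameter-recovery tests: φ = 0.2 recovered within [0.15, 0.25] at
  2000 features, Poisson data gives φ̂ < 0.01).
* **Exact test**: doubletail convention. Group pseudo-sums (a, b),
  conditional on t = a + b, are compared to the null distribution
  p(x)·q(t − x) with group sums NB(size n_g/φ, mean t·n_g/(n₁+n₂));
  the p-value sums all outcomes at most as probable as the observed one
  (with a 1+1e−10 tolerance on the probability comparison). φ = 0 uses
  the binomial limit. Pseudo-sums are rounded to integers for the
  enumeration. logFC = log2 of group means with a prior count of 0.125
  on the equalized scale (configurable), so zero groups stay finite.
  High-level class tables are normalized by total library size;
  TMM factors are reserved for refined-feature tables.
* **FDR**: Benjamini–Hochberg step-up (statsmodels), cross-checked
  against a hand implementation.

## tRNA fragments

No formal fragment classifier exists in the underlying description
(which reports 30–35-nt peaks and 33-nt 5′ halves), so the package
commits to testable thresholds: a fragment is a 5′ half when it starts
within 3 nt of the gene's 5′ end and is 28–36 nt long; 3′ halves mirror
this at the 3′ end; reads covering ≥ 90 % of the gene are full-length;
everything else is `other`. All three thresholds are keyword arguments.
Genes are taken as annotated genomic intervals, without modeling CCA
addition or intron splicing, because alignment is to the genome. The
four classes partition every tRNA call.

## Antisense complementarity search

Queries (tRNA fragment sequences, from the union of each sample's top-20
most abundant fragments) are matched by exact 6-mer reverse-complement
seeds and extended without gaps under +1/−3 scoring; the segment is
trimmed at both ends to the maximal raw score S (with additive scoring
the optimum containing the seed is the seed plus the best left and right
extensions independently). Duplicate extensions from overlapping seeds
are deduplicated by subject interval. The Karlin–Altschul parameters are
the documented ungapped values for +1/−3 nucleotide scoring, λ = 1.374
and K = 0.711; these reproduce the four distinct printed bit scores
(22.3, 26.3, 28.2, 32.2 for S = 11, 13, 14, 16) that pin the scoring
system. E-values use one fixed effective search space — the length of
the genomic union of all 3′ UTRs, so overlapping isoform UTRs count
once — with no per-query length adjustment; hits are kept at E ≤ 1.0.
N bases never match; queries over 20 % N are rejected.

Conservation of a hit is the arithmetic mean of a per-base phyloP-like
track over the hit's genomic footprint (mean rather than median or sum —
the convention is not fixed by the source material). The normalized
value divides by the mean over the shortest 3′ UTR overlapping the hit;
a `difference` mode (hit − UTR + 1) is selectable, as published
normalized values near 1 are consistent with either reading.

## Synthetic data

The generator emulates the study design end to end: six samples (two
tissues, cell and exosome conditions), one toy chromosome (100 kb)
carrying 10 miRNA precursors with 5p/3p arms, 8 snoRNAs, 3 each of
rRNA/miscRNA/snRNA (all ≤ 120 nt), 6 tRNAs (anticodons including Glu-CTC
and Gly-GCC), 2 piRNA clusters written as overlapping member intervals,
and 2 repeat families with 3 byte-identical copies each, plus planted
annotation overlaps (a miRNA inside a repeat, a snoRNA overlapping a
repeat) that exercise the cascade. A second contig holds eight 3′ UTRs
(two sharing a locus) with planted antisense sites for the tRNA halves:
a perfect 14-mer and a 20-mer with one interior mismatch whose flanks
are forced to mismatch so the planted extension is maximal.

Class mixtures: cells are dominated by miRNA (30 %) and snoRNA (26 %)
with 6 % tRNA; exosome mixtures scale the tRNA class fraction four-fold
among annotated classes and rescale the rest, so the only perturbed
class is tRNA (the compositional side-effect on other classes is
log2 0.8 ≈ −0.32, within the ±0.5 band the recovery tests allow). Read
lengths follow the class: mature-arm miRNA reads at 22 ± 1 nt, tRNA 5′
halves at 33 ± 2 nt anchored at the gene 5′ end, full-length tRNAs at
70–72 nt, piRNAs at 26–31 nt, other classes 20–40 nt. Fragment
composition is 20/70/10 (half/full/other) in cells and 70/30/0 in
exosomes. Class totals follow the mixture exactly (largest-remainder
apportionment); genes within a class are drawn multinomially, with
anticodon weights that put Glu-CTC at 60 % of cellular tRNA reads and
switch ASC exosomes to Gly-GCC. Default depth is 50 000 reads per
sample; tests use smaller depths (500–5000) where the property under
test does not need the full design, and the recovery checks use the full
six-sample, 50 000-read default.

All randomness flows from a single seeded generator, making FASTQ/SAM/
truth outputs byte-identical for a fixed seed. The generator writes
ground-truth SAM itself (it knows every equal-score placement), so no
aligner runs in the tests; FASTQ with appended adapter is still emitted
for users who want to run one.

What passing on this data shows — and does not. The simulation has exact
class counts, error-free reads, uniform qualities, no ligation bias, no
modification-induced truncations, and repeat copies that are perfectly
identical; recovery is therefore expected to be near-exact, and the
tests primarily establish that the bookkeeping (multi-mapping, cascade
order, normalization, conditioning) is correct, not that the pipeline is
robust to real-library noise. Dispersion estimation and the exact test
are exercised separately on NB-simulated counts with known φ.

## Known limitations

* The cascade resolves at gene-level records; multi-transcript GENCODE
  genes are collapsed to one record.
* The common-dispersion estimator uses linear library equalization, not
  the full quantile adjustment, and the exact test rounds pseudo-sums;
  with strongly unequal library sizes p-values can deviate slightly from
  the quantile-adjusted reference (the tests pin the equal-library case
  exactly).
* E-values use one global search space; published per-row e-values that
  imply per-query length adjustment are internally inconsistent with a
  fixed space, so only score-to-score e-value ratios are reproduced.
* No EM/probabilistic rescue of `Ambiguous` reads; no gapped or
  translated search; no tRNA-modification-aware correction.
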