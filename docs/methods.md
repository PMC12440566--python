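# Methods

This note documents the models, defaults and design choices behind
`bulktrap`, and what its synthetic-data tests do and do not demonstrate
about real bulk-sample data.

## Classification model

The classifier is a deliberately small analogue of minimiser-based k-mer
classification. Two simplifications relative to production tools:

* **Exact canonical k-mers, not window minimisers.** Every k-mer (default
  k = 31) is indexed, canonicalized as the lexicographic minimum of the
  k-mer and its reverse complement. Production classifiers subsample one
  minimiser per sliding window to shrink terabyte-scale indexes; at toy
  scale the subsampling changes memory, not semantics, so it is omitted.
  Strand symmetry is exact: classifying reverse-complemented reads yields
  identical reports (tested).
* **Index value = LCA of source species.** A k-mer found in several
  genomes maps to the lowest common ancestor of those species, so
  genus-shared sequence is reported at genus level.

Read assignment: hits are counted per taxon; every root-to-leaf path of
the taxonomy is scored by the summed hits on its nodes; the read is
assigned to the deepest node of the maximal path, and exact ties resolve
to the LCA of the tied leaves (identical genomes in two species therefore
classify to their common ancestor). Zero hits, or a read shorter than k,
is unclassified. K-mers spanning non-ACGT characters are skipped and
counted. Per-taxon reports carry clade read counts, total minimiser hits
and distinct minimiser counts; distinct minimisers per clade are the
distinct canonical k-mers whose index entry lies in the clade's subtree,
accumulated over classified reads only.

Sequential multi-database classification passes only still-unclassified
reads to the next database, which suppresses false positives from
conserved cross-kingdom sequence. Conservation is exact and tested: per
sample, classified reads summed over databases plus the final
unclassified count equals the input read count.

## Detection filtering

* **Spike floor.** Per sample, the threshold is the minimum clade
  distinct-minimiser count over the spike genera; a genus is present iff
  its count is **greater than or equal to** the floor. If every spike is
  zero the sample cannot be thresholded and an error is raised. Spike
  genera are excluded from all downstream matrices.
* **Barcode floor.** Metabarcoding presence needs ≥ 100 reads. The
  inclusive boundary mirrors the minimiser rule; the literature phrasing
  does not fix it, so it is a documented convention here (configurable).
* **Blank rule.** A taxon is excluded when it occurs in
  `floor(0.05 · n_blanks)` or more negative controls — 14 of 281. The
  count-based form is used because the published operationalization of
  "more than 5%" is 14-or-more at n = 281 even though 14/281 ≈ 4.98%;
  both the fraction and the comparison are parameters.
* **Placeholders.** Names equal to `unclassified` (case-insensitive) or
  carrying an `_X+` suffix (`Hominidae_X`, `Hominidae_XX`) mark unresolved
  genus-level taxonomy and are dropped. The filter is idempotent.

## Method comparison

Overlap is computed over genus-sample cells restricted to genera present
in both reference databases, with the metabarcoding detections as the
denominator: `both / (both + metabarcoding-only)`. The threshold sweep
re-binarizes the metagenomic reports at fixed global distinct-minimiser
thresholds in descending order; overlap is provably non-decreasing as the
threshold drops, and a mode is provided that prepends the per-sample
spike-calibrated thresholds to the sweep. The abundance test is a Welch
(unequal-variance) two-sided t-test on raw barcode counts, with an
optional log1p transform; when both groups are constant the statistic is
degenerate and is returned as t = 0/p = 1 (equal means) or ±inf/p = 0
(unequal), flagged rather than silently floored.

## Pooled mitochondrial pool-size inference

`make_pool_counts` draws, per site and individual, `Poisson(depth ×
weight)` observations of the haplotype base, substituted with probability
`error_rate` to a uniform other base. The reference defaults to the first
haplotype. The allele-frequency spectrum keeps sites with depth ≥
`min_depth` (default 5), takes the most frequent non-reference base as
the alternative allele, and excludes fixed sites at both ends, so a
single error-free haplotype yields an empty spectrum.

Spectra are compared as L1 distances between normalized 20-bin histograms
on (0, 1); the published analysis compared distributions visually, so the
metric is this package's choice (1-Wasserstein on raw frequencies is
available). Ties are reported, not broken, and the margin to the
runner-up is always returned because observed spectra rarely match any
simulated profile exactly.

Simulation conditions for the recovery analysis follow the pooled design
of 1, 2, 6 and 9 equally weighted individuals: mitogenome length 2,000 bp
(a desk-scale stand-in for a ~17-kb mitogenome), per-haplotype divergence
1% from a common ancestral sequence, depth 500X, sequencing error 0.2%.
Under these conditions the true pool size is recovered in ≥ 90% of
replicates (tested over 100); with nine individuals the private-variant
peak at 1/9 remains separable from 1/6 at depth 500.

## Heterozygosity, coverage, pseudo-haploid PCA

Windows tile the reference from position 1 as 1-based inclusive 10-kb
spans; the last window may be shorter and its covered-site denominator is
adjusted. A site is heterozygous when ≥ 2 distinct bases each reach
`min_minor` observations (default 2) at depth ≥ `min_depth` (default 5);
`min_minor = 1` reproduces the literal more-than-one-allele rule but is
error-sensitive at realistic error rates — the stricter default is this
package's choice because the upstream tools' thresholds are not published.
Mean coverage divides summed depth by reference length (absent sites are
depth 0); the structure-analysis gate keeps samples with coverage
strictly above 0.1X.

Pseudo-haploid calls draw one base per covered site with probability
proportional to its counts — an unbiased haploid representation for
low-coverage samples — coded 0/1 against the site's ref/alt alleles and
missing otherwise. PCA drops sites with MAF < 5% over non-missing calls,
mean-imputes missing values, centres columns and decomposes by SVD (not
the iterative genotype-likelihood estimator used at biobank scale, which
is unnecessary for pseudo-haploid calls at this size). Component signs
are fixed by making each component's first nonzero loading positive.

## Co-occurrence

Plant presence requires a per-species distinct-minimiser floor (default
5000; the acceptance run scales it to 1000 to match its smaller synthetic
genomes). "Most abundant" taxa are ranked by summed distinct minimisers
across samples with alphabetical tie-break. Pair counts are exact AND
counts over shared samples; the invariant `count ≤ min(prevalences)` is
checked on every build. Known interactions come from a local
plant × genus table — a stand-in for an external interaction database —
and annotation distinguishes confirmed pairs from pairs whose plant the
table does not cover at all.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the real inputs: a ranked
taxonomy, genome divergence that makes some k-mers genus-shared,
log-normal community abundances, uniform-position reads with independent
substitution errors, fixed-count spike-ins, multinomial barcode draws
with per-species capture bias, and Poisson-coverage pooled base counts.
It does not model indels, quality-score structure, PCR chimeras,
reference-database incompleteness, contamination, or uneven coverage
(GC bias, centromeric peaks). Passing tests therefore demonstrate the
correctness and internal consistency of the algorithms — conservation,
LCA soundness, threshold monotonicity, recovery under the stated noise
model — not field performance on real trap samples, where database gaps
and abundance skew dominate the error budget.

## Problem sizes

Tests and the acceptance run use communities of 6–10 genera × 2 species
(genomes 0.4–3 kb), 400–3,000 reads per sample across 3–6 samples,
100 pool-spectrum comparisons, and PCA panels of 20–30 samples × 400–500
sites; these sizes give stable statistics for every property tested while
keeping a full run to seconds.
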