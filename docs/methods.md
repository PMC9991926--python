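# Methods

This note documents the models and conventions implemented in `nzip`, the
choices made where several reasonable designs exist, and what the synthetic
benchmarks do and do not show.

## Library design

**Tiling.** A UTR of length L < 500 nt is tiled with 75-nt tiles every
15 nt; L ≥ 500 nt uses 100-nt tiles every 25 nt (the boundary L = 500 is
assigned to the large regime — a 500-nt UTR satisfies its constraints).
Tile starts are 0, offset, 2·offset, …; when the last regular tile does not
reach the end of the UTR, the remainder is absorbed into it as long as the
result stays ≤ 80 nt (small regime) or ≤ 110 nt (large regime). If
absorption would exceed that maximum, one extra right-anchored tile of the
regular size ending exactly at L is emitted instead, so the union of tile
intervals always equals [0, L). Coordinates are 0-based half-open
internally; exported tables also carry 1-based inclusive columns.

**Controls.** Scrambled controls are Fisher–Yates permutations of a source
tile (identical base composition) with a recorded seed; a permutation equal
to the source is resampled (homopolymers, for which no distinct permutation
exists, are returned as-is). Whether scrambles should preserve dinucleotide
content is an open design question; plain permutations are used.

**Adapters.** Every oligo is `TTCGATATCCGCATGCTAGC + tile +
GATCGGAAGAGCACACGTCT`. On the sequencing read the first adapter lies
*upstream* of the tile, immediately after the UMI; this orientation is the
one the read-processing layout requires and is used consistently.

**Candidate voting.** A gene qualifies when it has an enrichment value in
the reference system and either (a) significant enrichment (adjusted
p < 0.05) in ≥ 4 published datasets, median log2FC > 1, and (mean
log2FC > 1 or all-dataset-positive log2FC), or (b) significance in ≥ 5
datasets and any one of the three log2FC conditions. Statistics are
computed over datasets where the gene was measured. The downstream manual
curation of gene lists is out of scope.

## Mutagenesis design

Per parent tile of length L: all 3L single-base substitutions
(position-major, alternatives ordered A<C<G<T); complement-swap windows
(A↔T, C↔G applied to every base — an involution) of widths 2, 5 and 10 in
left-anchored, non-overlapping partitions with a truncated final window
(⌈L/w⌉ variants per width); one wild-type copy; three scrambles. Total
3L + ⌈L/2⌉ + ⌈L/5⌉ + ⌈L/10⌉ + 4. Sequences produced by more than one rule
are retained as separate records and flagged (`duplicate_sequence`) rather
than deduplicated, keeping library totals auditable.

## Read processing

Reads follow `UMI – adapter – tile – adapter`. Only reads containing the
upstream adapter exactly are used; the UMI is the fixed-length stretch
(default 10 nt — the UMI length is a protocol parameter, configurable)
immediately preceding it, and the insert is everything after it, truncated
at the first occurrence of the downstream adapter.

Matching is exact — no indels, and by default no mismatches, because
mutagenized libraries contain variants one substitution apart and any
mismatch tolerance would cross-assign them. Three match routes: insert
equals a tile; a tile is a prefix of the insert (the read ran into a
partially sequenced downstream adapter); the insert is a ≥ 40-nt prefix of
a tile (truncated read). If more than one tile matches, the read is
recorded as ambiguous, never assigned arbitrarily. Inserts containing N
fail matching (N is permitted in UMIs). Every read ends in exactly one of
{assigned, no_adapter, no_match, ambiguous}; the per-sample stats table
preserves this conservation, so the impact of each policy is visible.

UMI deduplication (default on, recorded in the stats) counts each
(tile, UMI) pair once per sample; the result is order-independent. Tiles
are retained downstream when their mean raw count across all samples is
≥ 20 (inclusive); the count of tiles with ≥ 20 reads in ≥ 3 samples is
reported as the detection summary.

## Enrichment model

Counts are modeled per tile as NB(μ, α) with Var = μ + αμ² and log-linear
mean with compartment (and optionally condition and compartment×condition)
covariates; log size factors enter as offsets.

* **Size factors** are median-of-ratios against the per-tile geometric
  mean, computed on tiles positive in all samples. Descriptive per-sample
  scaling for reporting is reads-per-million. When a large fraction of
  tiles carries true shifts, median-of-ratios absorbs part of the signal
  (a known property of global-scaling normalization); with realistically
  sparse effects (a few percent of tiles) the bias is negligible.
* **Dispersion** is estimated per tile by method of moments on normalized
  counts within each design cell, then moderated toward a trend
  α(μ) = a₀ + a₁/μ fitted by gamma-weighted IRLS across tiles, with weight
  prior_df/(prior_df + residual df), prior_df = 10. With triplicates
  (residual df 4) moderation is strong, which is what makes the Wald test
  usable at n = 3. Final values are clipped to [1e-8, 10].
* **Testing** is a Wald z test on the compartment coefficient (or the
  interaction coefficient for condition shifts), two-sided normal p,
  BH-adjusted; tiles whose GLM fit fails are flagged and excluded from the
  number of tests. The per-tile log2FC is the (unshrunken) GLM estimate;
  no independent filtering or outlier replacement is applied. This is a
  deliberate reimplementation in the style of the standard RNA-seq
  framework, not a byte-exact replication of any tool; an independent
  cross-check against pydeseq2 in the test suite confirms the group-mean
  log2FC estimates coincide and significance calls agree on simulated data.
* **Descriptive ratios** per replicate are log2((neurite + 0.5)/(soma +
  0.5)) on normalized counts; the 0.5 pseudocount keeps 0/0 pairs at 0.
  The model-based and descriptive estimates agree within 0.25 log2 units
  for well-covered tiles on simulated data (tested).
* **Calling**: neurite-localized = log2FC ≥ 1 and adjusted p < 0.1;
  condition shifts significant at adjusted p < 0.05. All thresholds
  (20 reads, 1.0, 0.1, 0.05) are configurable defaults, not constants.
* **Group comparisons** use the two-sided Wilcoxon rank-sum test: exact
  enumeration when both groups have ≤ 25 untied observations, otherwise the
  tie-corrected normal approximation; the method used is returned.
* **QC**: pairwise Spearman correlations of raw counts within compartment
  (warning below 0.85); endogenous RNA-seq genes are retained when
  log2(exon/intron) > 2.5 and log2(sense/antisense) > 2, with a 0.5
  pseudocount on each term so zero-intron genes stay finite (the
  pseudocount is this package's choice; the thresholds are the standard
  ones for this QC).

Sign conventions: positive log2FC = neurite-enriched; positive condition
shift Δlog2FC = more neurite-enriched under the treatment condition.

## Motif scanning and association

* A miRNA **7mer site** is the DNA reverse complement of mature positions
  2–8 (for the let-7 family: CTACCTC); the **8mer** appends an A opposite
  position 1 (CTACCTCA). 7mer-A1 sites are not counted as a separate
  class. Families with identical positions 2–8 collapse to one entry.
  Occurrences are counted allowing overlap.
* **(AU)ₙ** is the largest n with ("AT")ⁿ as an exact substring; any
  interruption resets the run. Phase is irrelevant in effect because a
  longer alternating run contains the in-phase repeat.
* **CPE** defaults to the consensus TTTTAT (configurable set, e.g. adding
  TTTTAAT/TTTTTAT); flags are reported for the whole sequence and for the
  last 30 nt, where the element is most active.
* Association analyses: enrichment CDF groups (let-7 0 / ≥1 7mer / ≥1 8mer,
  or 0/1/>1 sites, or (AU)0–5 vs (AU)6+) compared pairwise by rank-sum;
  per-family volcano = mean log2FC of site-bearing tiles with a two-sided
  t test against site-free tiles, significance at p < 0.05 (families
  without ≥ 2 tiles on each side are skipped).
* Endogenous transcripts: per gene, the most abundant isoform (highest
  summed average TPM across compartments; ties broken by transcript id) is
  kept when that sum is ≥ 10; localization = log2((mean neurite TPM + 1)/
  (mean soma TPM + 1)); perturbation shifts are differences of these ratios
  between conditions.

## Synthetic data

The generator emulates the study design: ~99 UTRs of 200–2,000 nt,
neurite/soma triplicates, NB counts, 10-nt UMIs, 150-nt single-end reads.
Motifs (CTACCTC ×1–3, (AT)ₙ with n ∈ 6–8, TTTTAT) are implanted at
non-overlapping random positions with per-gene probability 0.2 each —
roughly the fraction of motif-positive transcripts seen in this system.
Effects are specified directly on the log2 neurite/soma ratio and split
symmetrically across compartments (soma mean ×2^(−e/2), neurite ×2^(+e/2)),
a reduced form of the soma-biased destabilization mechanism; per-let-7-site
effect 1.0 and (AT)6+ effect 1.5 log2 units, matching the magnitude of
enrichment seen for localized tiles. Motif-free tiles are pure null
(optional jitter available). Baseline abundances are log-normal(0, 1);
dispersion defaults to 0.05; sequencing error 0.001/base; PCR duplication
0.1 (duplicates share the molecule's UMI). Knockdown/depolarization-style
perturbations multiply motif effects by an attenuation factor in [0, 1].

UMIs are drawn *distinct* within each (sample, tile), so the molecule truth
table is exact; real UMI-space collisions are not emulated. Reads are
emitted deterministically given (config, seed); FASTQ bytes are
reproducible.

What passing the synthetic benchmarks shows: the counting path is exact in
the error-free limit; the NB Wald test is calibrated and recovers implanted
effects at realistic depth and dispersion; the motif association analyses
detect implanted motif–localization coupling in the right direction. What
it does not show: robustness to real-data pathologies the generator omits —
fragment-specific amplification bias, secondary-structure-dependent
coverage, astrocyte contamination, cross-mapping between homologous UTRs,
or dispersion trends steeper than the fitted 1/μ form.

## Benchmark problem sizes

The statistical benchmarks (also run by `scripts/acceptance.py`) use:
null calibration — 2,000 tiles, triplicate compartments, dispersion 0.05,
depth 10⁶, rejection measured at raw p < 0.05; effect recovery — 20
independent experiments of 2,000 tiles with 40 tiles per effect level
(log2FC 1 and 2, 4% of tiles, uniform coverage ≈ 500 reads/tile), pooled to
800 tiles per level, reporting the median absolute estimation error and the
fraction of effect-2 tiles called at log2FC ≥ 1 & padj < 0.1. Uniform
baselines are used there so the measurement targets estimator precision at
the nominal depth rather than the coverage distribution. At triplicate
scale the Wald test is mildly anticonservative (rejection ≈ 0.055 at
α = 0.05 across seeds), the expected finite-sample behavior of Wald tests
with moderated dispersions; the recovery error (~0.18 log2 units median)
sits close to the dispersion-limited floor √(2α/3)/ln 2 · Φ⁻¹(0.75).

## Known limitations

* The NB test is not a byte-exact DESeq2 replication: no Cook's-distance
  outlier handling, no independent filtering, normal-tail Wald p only.
* Exact matching discards reads from mutated positions at higher error
  rates; the stats table quantifies the loss but no error-tolerant mode
  re-assigns them.
* The candidate voting operates on provided enrichment tables; acquiring
  and harmonizing the published datasets is upstream of this package.
* Scrambled controls are composition-preserving only.
* The paper-scale totals (oligo-pool size, detection counts on deposited
  sequencing runs) require the original supplementary inputs and are not
  recomputed here; all benchmarks are generator-based.
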