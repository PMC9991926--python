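# nzip

Design and analysis toolkit for tiled massively parallel reporter assays
(MPRAs) that map mRNA *zipcodes* — the 3′ UTR elements that direct
transcripts to subcellular compartments such as neurites versus soma.

The experimental idea this package supports: candidate 3′ UTRs are cut into
overlapping ~75–110-nt tiles, each tile is placed behind a reporter between
constant adapters, the pooled library is expressed in neurons grown on a
microporous membrane, and amplicon sequencing of RNA from separated neurites
and soma reads out which tiles are sufficient to drive localization. A
follow-up library saturates the hit tiles with every single-base substitution
and with A↔T/C↔G swap windows to fine-map the responsible motifs (miRNA seed
sites such as the let-7 site CUACCUC, and (AU)ₙ dinucleotide repeats).

`nzip` covers the computational protocol end to end:

| module | what it does |
| --- | --- |
| `nzip.library_design` | tiling of UTRs (75 nt / 15-nt offset below 500 nt, 100 nt / 25-nt offset above; remainder absorbed into the last tile), scrambled controls, adapter assembly, candidate-gene voting rules |
| `nzip.mutagenesis` | saturation variants: 3L single substitutions + ⌈L/2⌉+⌈L/5⌉+⌈L/10⌉ swap windows + wild-type + 3 scrambles per parent |
| `nzip.read_processing` | UMI–adapter–tile read parsing, indel-free matching, UMI deduplication, ≥20-mean-read detection filter |
| `nzip.enrichment` | per-sample normalization, per-replicate pseudocount log-ratios, NB Wald neurite/soma test with BH correction, condition-shift (interaction) tests, Wilcoxon group comparisons, Spearman replicate QC |
| `nzip.motifs` | miRNA 7mer/8mer seed-site scanning, maximal (AU)ₙ, CPE flags, motif–localization association (CDF groups, per-family volcano, endogenous TPM analyses) |
| `nzip.simulate` | ground-truth generator: UTRs with implanted motifs, NB counts under a soma-destabilization model, FASTQ with UMIs, sequencing errors and PCR duplicates |

## The statistics in brief

Counts for tile *i* in sample *j* are modeled as negative binomial,
Var = μ + αμ², with a log-linear mean

μ<sub>ij</sub> = s<sub>j</sub> · exp(β₀ᵢ + β₁ᵢ·neurite<sub>j</sub> [+ β₂ᵢ·cond<sub>j</sub> + β₃ᵢ·neurite<sub>j</sub>·cond<sub>j</sub>])

where s<sub>j</sub> are median-of-ratios size factors. β₁/ln 2 is the
neurite/soma log2 fold change; condition shifts are tested on the
interaction β₃. Dispersions are method-of-moments estimates moderated toward
a fitted mean–dispersion trend α(μ) = a₀ + a₁/μ, and coefficients are tested
with a Wald z statistic, BH-adjusted across tiles. Tiles with log2FC ≥ 1 and
adjusted p < 0.1 are called neurite-localized. Group comparisons (e.g. tiles
with vs without let-7 sites) use the two-sided Wilcoxon rank-sum test, exact
for small untied samples.

## Worked example

Simulate a 40-gene experiment with implanted let-7 sites and (AU)ₙ repeats,
count the reads, and test enrichment:

```python
from nzip import (SimConfig, simulate_experiment, count_reads,
                  filter_detected_tiles, nb_wald_localization,
                  call_localized_tiles, annotate_sequences, group_shift_test)

cfg = SimConfig(n_genes=40, utr_len_min=200, utr_len_max=800,
                depth=2e5, seed=7)
res = simulate_experiment(cfg, outdir="sim/fastq", write_fastq=True)
table, stats = count_reads(res["sample_sheet"], res["library"])
print(f"assigned {stats['assigned'].sum():,} of {stats['total'].sum():,} reads")

table, summary = filter_detected_tiles(table)
print(f"{summary['n_tiles_retained']}/{summary['n_tiles_total']} tiles pass the 20-read filter")

enr = call_localized_tiles(nb_wald_localization(table))
print(f"{int(enr['localized'].sum())} tiles called neurite-localized "
      f"(log2FC >= 1, padj < 0.1)")

ann = annotate_sequences(res["library"].set_index("tile_id")["sequence"]).loc[enr.index]
has = ann["let7_sites7"] >= 1
p, _ = group_shift_test(enr.loc[has, "log2fc"], enr.loc[~has, "log2fc"])
print(f"let-7 site tiles: n={int(has.sum())}, median log2FC "
      f"{enr.loc[has,'log2fc'].median():.2f} vs {enr.loc[~has,'log2fc'].median():.2f} "
      f"(rank-sum p = {p:.1e})")
```

Output:

```
assigned 1,097,897 of 1,338,942 reads
894/939 tiles pass the 20-read filter
29 tiles called neurite-localized (log2FC >= 1, padj < 0.1)
let-7 site tiles: n=47, median log2FC 0.93 vs -0.04 (rank-sum p = 5.7e-28)
```

Reads carrying sequencing errors fail the exact (indel-free, mismatch-free)
matching and are reported in the per-sample stats; tiles bearing a single
implanted let-7 site sit about one log2 unit above motif-free tiles, the
implanted per-site effect.

A command-line interface mirrors the pipeline stages:

```sh
nzip design --utrs utrs.fa --out library.tsv --seed 17 --controls Camk2a,Actb,Bc1
nzip mutate --parents tiles.tsv --out mut_library.tsv --seed 17
nzip count  --library library.tsv --samples samples.tsv --out counts.tsv
nzip enrich --counts counts.tsv --samples samples.tsv --out enrich.tsv
nzip simulate --out simdir --seed 5
```

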