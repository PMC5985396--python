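# arasig

Toolkit for profiling the genomic loci of androgen-receptor-associated
lincRNAs (ARA-lincRNAs) against a matched non-associated control set
(NonA-lincRNAs). The pipeline covers:

- **`synthetic_data`** — a synthetic study generator (annotations, epigenetic
  read tracks, RIP-seq / RNA-seq count matrices, FPKM, TADs) with full ground
  truth, so every downstream stage has a parameter-recovery test.
- **`count_model`** — self-contained negative-binomial enrichment/DE testing
  (median-of-ratios size factors, method-of-moments dispersion, Wald test,
  Benjamini–Hochberg FDR), ARA calling (log2(antiAR/IgG) > 0, FDR < 10%),
  DE calling (q < 0.05, |FC| ≥ 2) and the matched NonA control-set
  construction (ascending |log2fc| after zero-count exclusion).
- **`genome_intervals`** — GTF/BED I/O, strand-aware ±500 bp TSS windows,
  reads-per-million window counts, union-mode exon counting, closest-TSS
  neighbor pairing, and the novel-lincRNA filter rules (≥ 200 nt, FPKM ≥ 1,
  intergenic, longest-ORF coding filter).
- **`peak_caller`** — peak significance against a local 10-kb Poisson
  background, BH-filtered at FDR < 0.001.
- **`signature_ml`** — TSS epigenetic feature encoding, warm-started random
  forests over a tree grid with 5-fold CV and OOB scoring, and the
  shuffled-label Gini-importance null (per-feature 95th-percentile cutoff,
  enrichment directions).
- **`tad_profile`** — TAD assignment by TSS, per-TAD peak-count comparisons,
  the normalized boundary-distance metric (0% at a boundary, 100% at the TAD
  middle) and TAD-level expression comparisons.
- **`enhancer_profile`** — H3K27ac/H3K27me3 promoter ratio with a one-sided
  KS comparison, the enhancer-mark stringency correlation ladder,
  peak-to-TSS distance distributions and neighbor-expression response
  comparisons gated on PolII presence.
- **`pipeline`** — orchestration of all stages into one JSON report,
  including the androgen-activated / -inhibited neighbor subset bookkeeping.

## CLI

```sh
# generate a synthetic study with known ground truth
arasig simulate --out study/ --seed 1

# run the full analysis on it
arasig run --study study/ --out results/ --trees 100,500,1000 --shuffles 200

# or end-to-end from a config (defaults used when --config is omitted)
arasig run --config config.json --out results/

# individual stages
arasig rip-call --counts study/rip_counts.tsv --conditions study/rip_conditions.json --out rip.tsv
arasig de-call  --counts study/rnaseq_counts.tsv --conditions study/rnaseq_conditions.json --out de.tsv
arasig neighbors --gtf study/annotation.gtf --out neighbors.tsv
arasig peaks --reads study/tracks/H3K27ac.bed --mark H3K27ac --fdr 0.001 --out peaks.bed
```

`arasig run` writes `report.json` plus TSV tables (neighbor pairs, feature
matrix, enrichment/DE tables, per-TAD peak counts) to the output directory.
The default tree grid (100/500/1000) and shuffle count (200) are scaled down
from the reference procedure (grid up to 10000 trees, 1000 shuffles); pass
`--trees 100,500,1000,10000 --shuffles 1000` for the full-size run.

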