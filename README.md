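# bipair

Strand-aware analysis of **bidirectionally transcribed gene pairs** and
**RNA polymerase II pausing**, for transcriptomics studies that ask whether a
perturbation preferentially affects genes driven by divergent (head-to-head)
promoters.

The package is aimed at computational biologists working with bulk RNA-seq /
nascent-RNA (4sU-seq) / Pol II ChIP-seq data who need, in one place:

- **Gene-pair annotation** — for every protein-coding gene, the nearest
  neighbour in each direction × orientation category
  (`upstream_antisense`, `upstream_sense`, `downstream_antisense`,
  `downstream_sense`), by genomic gap distance, with a configurable proximity
  threshold (default < 1 kb). A gene with an `upstream_antisense` partner
  < 1 kb away sits in the classic bidirectional-promoter configuration.
- **Bidirectional-promoter calls** — opposite-strand initiation evidence
  (CAGE peaks or antisense read coverage) within a window upstream of the TSS
  (default 100 nt).
- **Pol II pausing** — the travelling ratio
  `TR = reads in [TSS, TSS+250) / reads in [TSS+250, TES)`,
  plus scaled-region and reference-point metagene matrices and a
  reference-gene normalization that removes ChIP-efficiency differences
  between libraries (subtract the gene-body baseline of high-expressed
  unchanged genes, then scale by their TSS ± 1 kb mean).
- **Intron/exon coverage ratios** — median-of-ratios size factors from exonic
  counts, then per-gene mean intron coverage / mean exon coverage with the
  standard degenerate-value substitutions (no exon signal → 1, (nearly) no
  intron signal → 0.001), as an intron-retention readout.
- **Enrichment statistics** — up/down/unchanged DE classes
  (|log2FC| > 0.3, padj < 0.05 by default), fold enrichment of pair
  categories with two-sided Fisher's exact tests, gene-set resampling null
  bands (e.g. the 99.9% CI of 10,000 random subsets), expression ECDFs.
- **A synthetic-data generator** — genomes with a planted fraction of
  divergent pairs, log-normal expression, a promoter-proximal pausing peak,
  antisense initiation at bidirectional promoters, intronic reads, and a
  knock-down condition that represses high-expressed divergent genes; every
  planted quantity is recorded in a truth table so each estimate can be
  scored exactly.

All interval arithmetic is 0-based half-open; GTF I/O converts at the
boundary, BED/bedGraph pass through unchanged.

## Worked example

Simulate a study in which a knock-down represses high-expressed divergent
genes, then ask whether repressed genes are enriched for upstream antisense
partners:

```python
from bipair import (SimConfig, generate_annotation, simulate_coverage,
                    simulate_de_table, classify_de, annotate_pairs,
                    fold_enrichment)

cfg = SimConfig(n_genes=800, seed=42)
genes, truth = generate_annotation(cfg)
ctrl = simulate_coverage(genes, truth, cfg, "control")
kd = simulate_coverage(genes, truth, cfg, "knockdown")
de = classify_de(simulate_de_table(ctrl["exon_counts"], kd["exon_counts"]))
down = de.loc[de.de_class == "down", "gene_id"]

res = fold_enrichment(annotate_pairs(genes), down, "upstream_antisense")
print(f"{len(down)} repressed genes out of {len(de)}")
print(f"fraction with an upstream antisense partner <1 kb: "
      f"{res['frac_class']:.2f} (class) vs {res['frac_universe']:.2f} (all)")
print(f"fold enrichment = {res['fold']:.2f}, Fisher p = {res['p_value']:.2e}")
```

prints

```
72 repressed genes out of 800
fraction with an upstream antisense partner <1 kb: 0.99 (class) vs 0.17 (all)
fold enrichment = 5.89, Fisher p = 1.24e-62
```

72 of 800 genes are classified as repressed; 99% of them have a
protein-coding neighbour head-to-head within 1 kb versus 17% of all genes, a
5.9-fold enrichment — the signature the pipeline is designed to detect (the
planted effect here targets divergent high-expressed genes, so the
enrichment is strong by construction).

The same stages are available from the shell:

```bash
bipair simulate --seed 5 --out data/
bipair run --sim-dir data/ --out-dir results/
bipair pairs --gtf annotation.gtf --max-dist 1000 --out-dir pairs/
bipair pausing --gtf annotation.gtf --bedgraph polii.plus.bedgraph --out-dir tr/
```

Every subcommand writes a JSON run manifest (command, config snapshot, input
checksums, seed, version); deterministic commands re-run byte-identically.

## Applying it to real data

`bipair annotate --gtf gencode.gtf --biotype protein_coding --out-dir ann/`
runs exon classification (first / internal / last labels per transcript
position, unioned per unique exon, with the exclusively-first subset),
intron derivation and promoter windows on any Gencode-style GTF; the
header of `exon_classification.tsv` reports the total exon-annotation and
exclusively-first counts. `bipair enrich` consumes any DE table with
`gene_id`, `mean_expression`, `log2FC`, `padj` columns, so externally fitted
differential-expression results drop in directly.

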