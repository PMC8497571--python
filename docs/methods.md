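# Methods

## The analysis model

The pipeline quantifies whether a gene class (typically genes repressed by a
perturbation) is enriched for the **bidirectional-promoter configuration**:
a protein-coding gene with another protein-coding gene head-to-head
(upstream, antisense) within a short distance. The chain of stages:

1. **Gene models** are parsed from Gencode-style GTF into 0-based half-open
   coordinates. The gene-level TSS is the 5'-most transcript start in
   transcription orientation; with half-open coordinates the TSS of a
   minus-strand gene is its span end, so `[tss - w, tss)` is always the
   `w` bp immediately upstream regardless of strand.
2. **Pair annotation.** For each gene, the nearest neighbour in each of the
   four direction × orientation categories. Distance is the genomic gap
   between gene spans; overlapping or abutting spans count as 0 and are
   retained rather than excluded. Which side a neighbour lies on is decided
   by span midpoints (ties broken by gene id), which makes the
   classification invariant under mirroring all coordinates and strands.
   A neighbour "counts" when its gap is strictly below `pair_max_dist`
   (default 1000 bp). Gap distance equals TSS-TSS distance for
   non-overlapping divergent pairs up to each gene's span convention; a
   TSS-to-TSS metric would differ only by the partners' span extents.
3. **Bidirectional calls.** A gene is called bidirectionally initiated when
   opposite-strand evidence (a stranded peak, or summed antisense coverage
   above a threshold, default > 0) falls in the `antisense_window`
   (default 100 nt) immediately upstream of its TSS on the opposite strand —
   the region a divergent transcript initiates into. A ± window centred on
   the TSS is available (`centered=True`) for sensitivity analysis.
4. **DE classes.** up: log2FC > 0.3 and padj < 0.05; down mirrored; strict
   inequalities; everything else unchanged. Missing padj leaves a gene
   unclassified.
5. **Enrichment.** fold = P(category | class) / P(category | universe), with
   a two-sided Fisher's exact test on the 2×2 table (class membership ×
   neighbour status). Two-sided means summation of all tables with point
   probability ≤ the observed one (the standard convention). p-values are
   per category; no correction is applied across the four categories, and
   the output says so.
6. **Pausing.** Travelling ratio = reads in `[TSS, TSS + 250)` / reads in
   `[TSS + 250, TES)`, both in transcription orientation. Genes not longer
   than the window are excluded with a log entry; zero body signal yields an
   infinite, flagged ratio rather than a silent drop.
7. **Metagene matrices.** Scaled-region layout: 1000 bp upstream flank,
   1000 bp unscaled 5', gene body linearly rescaled to 500 bp, 500 bp
   unscaled 3', 500 bp downstream flank, averaged into 10-bp bins (350
   columns). Reference-point layout: `[anchor - b, anchor + a)` at 1-bp (TSS,
   b = a = 500) or 10-bp (accessibility profiles, b = a = 3000) bins.
   Minus-strand rows are reversed so transcription always runs left to
   right. Bin values are means over covered bases; a partial final bin is
   averaged over its actual width. Body rescaling is linear interpolation,
   so constants are preserved exactly and the operation is linear in the
   track.
8. **Reference-gene Pol II normalization.** Given a scaled matrix and a set
   of high-expressed unchanged genes: β = mean over those genes of the
   scaled-body bins only (the unscaled 5'/3' segments are the TSS/TES
   proximal regions and are excluded by construction); μ = mean of their
   TSS ± 1 kb bins *after* subtracting β. Output = (matrix − β)/μ. The μ
   window is exactly the upstream flank plus the first unscaled kilobase
   (columns 0–200). Properties (tested exactly): unchanged-gene TSS ± 1 kb
   mean is 1 after normalization; adding a constant or rescaling the track
   leaves the result unchanged; re-applying with the same reference is the
   identity (β = 0, μ = 1). μ ≤ 0 raises — it means the reference set has no
   TSS signal above its own gene-body baseline, and normalizing by it would
   be meaningless. The "unchanged" set is selected as |log2FC| < 0.3 **and**
   padj > 0.5, ranked by mean expression (top n, default 199, ties broken by
   gene id) — an equivalence-style approximation that avoids re-fitting a
   shifted-null test; it is conservative in that it requires both a small
   point estimate and a clearly non-significant test.
9. **Intron/exon ratios.** Size factors are median-of-ratios over genes with
   nonzero counts in every sample, computed from exonic counts only. Genes
   must pass mean CPM > 20 (exonic counts; an exon+intron CPM variant was
   considered and rejected to keep the filter consistent with the size
   factors). Ratio = (intron count / intron length) / (exon count / exon
   length) on size-factor-normalized means. Degenerate genes are
   substituted, not dropped: no exon signal → 1.0 (`no_exon->hi`), zero
   intron counts or ratio < 0.001 → 0.001 (`low_intron->lo`) — "nearly no
   intron counts" is quantified as falling below the floor itself, which
   reproduces the substitution without inventing a second threshold.
10. **Resampling null band.** `n_resample` (default 10,000) subsets of the
    class size are drawn without replacement from the matrix rows; the band
    is the per-column nearest-rank `[(1-ci)/2, 1-(1-ci)/2]` percentile of
    the subset mean profiles (ci = 0.999 by default). Nearest-rank rather
    than interpolated percentiles keeps the band bit-reproducible across
    platforms. "Similar size" is implemented as *exactly* the class size.

## Synthetic data: what it emulates, and what it does not

`SimConfig` defaults define the study regime:

| parameter | default | meaning |
|---|---|---|
| `n_genes`, `n_chromosomes` | 1000, 5 | gene universe |
| `fraction_divergent` | 0.15 | fraction of genes planted in head-to-head pairs |
| `divergent_dist_min/max` | 100–900 bp | log-uniform TSS–TSS gap of planted pairs (inside the 1 kb threshold) |
| `intergenic_min/max` | 5–20 kb | log-uniform gaps between unrelated gene units (outside the threshold) |
| `expression_mu/sigma` | ln-scale 4.0 / 1.5 | log-normal expression spanning ~3 orders of magnitude |
| `tr_mu/sigma` | ln-scale 1.4 / 0.8 | log-normal travelling ratios, median ≈ 4 |
| `antisense_fraction_at_divergent` | 0.9 | divergent genes carrying opposite-strand initiation reads |
| `intron_ratio_mu/sigma` | ln-scale −3.0 / 0.5 | baseline intron/exon coverage ratio ≈ 0.05 |
| `kd_log2fc_mean/sigma` | −1.0 / 0.25 | knock-down effect on targets |
| `kd_retention_log2` | 1.0 | intron-retention shift on targets under knock-down |
| `target_expression_quantile` | 0.5 | targets = divergent genes above this expression quantile |
| `depth`, `n_replicates`, `read_length` | 5×10⁵, 4, 50 | sequencing scale |

Reads are Poisson per replicate and represented as fragment intervals (no
sequences; alignment is out of scope). A fraction TR/(1+TR) of each gene's
sense reads starts in the promoter window, the rest uniformly over the body,
realizing the planted travelling ratio in expectation. Genes flagged for
antisense signal emit at least one opposite-strand read wholly inside the
100-nt upstream window, so planted bidirectionality is recovered with recall
and precision 1 — by construction, the flag and the emitted signal cannot
disagree. Chromosome lengths are auto-sized to 3× the per-chromosome gene
footprint (never shorter than the last gene end plus a margin), so
placement can never run off the end and a genome-too-small failure mode does
not arise.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: overdispersion beyond Poisson (real biological
replicates are noisier, so real DE calls are harder), overlapping and nested
genes, multi-TSS genes with isoform switching, mappability and GC artefacts,
eRNA/enhancer transcription, and any coupling between pausing and expression
beyond independence. The DE stand-in (`simulate_de_table`: size-factor
normalized means, exact binomial test of the knock-down read share,
Benjamini–Hochberg adjustment) is deliberately simple plumbing for the
pipeline's inputs; it is not a negative-binomial model and is never used as
one.

## Numerical choices

- Percentiles in the null band: nearest-rank (determinism across platforms).
- Size-factor median taken in linear ratio space (matching the standard
  median-of-ratios definition; a log-space median differs for even counts).
- Binning: mean over covered bases; partial end bins averaged over actual
  width.
- Tie-breaks everywhere are lexicographic by gene id (neighbour ties,
  unchanged-gene ranking), making outputs deterministic.
- Degenerate inputs: empty signal → all-false bidirectional calls; genes
  shorter than the pausing window excluded with a log line; windows running
  off a chromosome are clipped (promoters) or zero-padded (metagene rows);
  unstranded signal where strand is required raises.
- Per-stage seeds are derived from a master seed by hashing
  `(master, stage name)` (SHA-256, reduced below 2³¹), so stages are
  independently reproducible and insensitive to execution order.

## Design choices made where the design was open

- **Distance metric:** genomic gap between spans (overlap → 0) rather than
  TSS-to-TSS; it handles all four categories uniformly and is the only
  metric that degrades gracefully for overlapping genes. TSS–TSS distances
  are recoverable from the annotation when needed.
- **Intron derivation** subtracts the union of exons over *all* transcripts
  of a gene from the gene span, so no exonic base of any isoform is counted
  as intron.
- **Exon identity** for the exclusively-first classification is exact
  (chrom, start, end) within a gene; the same coordinates appearing in two
  genes are counted per gene.
- **Antisense window placement:** upstream of the TSS on the opposite strand
  (where divergent initiation occurs) by default; the centred variant exists
  because peak-based datasets sometimes place peak summits downstream of the
  annotated TSS.
- **Frequency-difference testing** between a DE class and the universe uses
  Fisher's exact test on the neighbour-status table; no correction across
  the four categories (single-category claims), flagged in the output.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
studies of 300–2000 genes, depths of 10⁵–2×10⁶ reads per sample, 10,000-draw
null bands, and 100-seed recovery sweeps — sizes chosen so every stage's
statistical behaviour (oracle equivalence, closed forms, planted-effect
recovery within stated tolerances, null calibration at nominal levels) is
measurable in minutes on one CPU. Exact-count checks against a full human
annotation (e.g. total and exclusively-first exon counts on Gencode v19) run
through the same `classify_exons` code path via
`bipair annotate --gtf <gencode.gtf>`; they require the user to supply the
GTF and take a couple of minutes.

## Known limitations

- No GFF3 input (GTF only); no BAM input in v1 — fragments come as BED-like
  tables, coverage as bedGraph.
- Gene-level TSS collapses multi-TSS genes to the 5'-most start.
- The enhancer definition (histone-mark peaks clear of promoters) is purely
  positional; no activity filtering.
- `fragments_to_coverage` RPKM-like scaling assumes a single fragment
  population (one mean length).
- The Fisher test treats genes as exchangeable; spatial autocorrelation
  along chromosomes (gene clusters) is not modelled, which can make
  p-values anti-conservative on real genomes. The resampling band is the
  provided remedy for profile-level comparisons.
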