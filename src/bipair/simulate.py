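"""Synthetic genomes, coverage and counts with planted ground truth.

The generator emulates the statistical regime the analysis assumes: a
genome whose protein-coding genes are partly arranged as head-to-head
(divergent) pairs at sub-kilobase TSS-TSS distances, log-normal expression,
a promoter-proximal pausing peak, opposite-strand initiation signal at
bidirectional promoters, an intronic read fraction, and a knock-down
condition that preferentially represses high-expressed divergent genes
(with an intron-retention side effect on the same targets).  Every planted
quantity is recorded in a truth table so each downstream estimate can be
scored against a named truth column.

Read counts are Poisson per replicate; reads are represented as fragment
intervals (no sequences).  All draws are reproducible from the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import GeneModel, TranscriptModel
from .config import AnalysisConfig, DEFAULT_CONFIG
from .coverage import CoverageTrack


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study.

    Defaults describe the regime the pipeline targets: ~15% of genes in
    divergent pairs initiated < 1 kb apart, log-normal expression spanning
    ~3 orders of magnitude, log-normal travelling ratios around 4, and a
    knock-down that represses high-expressed divergent genes by ~1 log2
    unit while increasing their intron retention.
    """

    n_genes: int = 1000
    n_chromosomes: int = 5
    fraction_divergent: float = 0.15
    divergent_dist_min: int = 100          # TSS-TSS gap, log-uniform draw
    divergent_dist_max: int = 900
    intergenic_min: int = 5000             # gap between unrelated gene units
    intergenic_max: int = 20000
    gene_len_min: int = 2000
    gene_len_max: int = 10000
    expression_mu: float = 4.0             # ln-scale mean reads/sample
    expression_sigma: float = 1.5
    tr_mu: float = 1.4                     # ln travelling ratio ~ N(1.4, 0.8)
    tr_sigma: float = 0.8
    antisense_fraction_at_divergent: float = 0.9
    antisense_rate: float = 0.05           # antisense reads per sense read
    intron_ratio_mu: float = -3.0          # ln intron/exon coverage ratio
    intron_ratio_sigma: float = 0.5
    kd_log2fc_mean: float = -1.0           # effect on targeted genes
    kd_log2fc_sigma: float = 0.25
    kd_retention_log2: float = 1.0         # intron-retention shift on targets
    target_expression_quantile: float = 0.5  # targets are divergent genes above this
    read_length: int = 50
    n_replicates: int = 4
    depth: float = 500_000.0               # expected reads per sample
    seed: int = 0

    def __post_init__(self):
        for f in ("fraction_divergent", "antisense_fraction_at_divergent",
                  "target_expression_quantile"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ValueError(f"{f} must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# annotation with planted pairs
# ---------------------------------------------------------------------------

def _make_gene(gene_id: str, chrom: str, strand: str, start: int, length: int,
               n_exons: int, rng: np.random.Generator) -> GeneModel:
    """One gene with a single transcript of 1-3 exons covering ~40% of the span."""
    end = start + length
    exonic = max(int(0.4 * length), n_exons * 100)
    cuts = np.sort(rng.choice(np.arange(1, n_exons), size=n_exons - 1,
                              replace=False)) if n_exons > 1 else np.array([], int)
    exon_lens = np.diff([0, *(exonic * cuts // n_exons), exonic])
    exon_lens = np.maximum(exon_lens, 50)
    intronic = length - int(exon_lens.sum())
    if n_exons == 1 or intronic <= 0:
        exons = [(start, end)]
    else:
        gap = intronic // (n_exons - 1)
        exons = []
        pos = start
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el) + (gap if i < n_exons - 1 else 0)
        # stretch the last exon to the gene end so span is covered
        exons[-1] = (exons[-1][0], end)
    tx = TranscriptModel(transcript_id=f"{gene_id}.t1", exons=exons)
    return GeneModel(gene_id=gene_id, gene_name=gene_id.replace("GENE", "Name"),
                     chrom=chrom, strand=strand, start=start, end=end,
                     biotype="protein_coding", transcripts=[tx])


def generate_annotation(cfg: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[list[GeneModel], pd.DataFrame]:
    """Place genes with the requested fraction of head-to-head pairs.

    Divergent pairs are planted as a minus-strand gene immediately upstream
    (head-to-head) of a plus-strand gene, TSS-TSS gap drawn log-uniformly
    from [divergent_dist_min, divergent_dist_max]; unrelated gene units are
    separated by log-uniform intergenic gaps well beyond the pairing
    threshold.  Returns the gene models and a truth table with the planted
    pair structure, expression, travelling ratio, intron ratio, antisense
    flag and knock-down effect per gene.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    n_pairs = int(rng.binomial(n // 2, cfg.fraction_divergent))
    n_single = n - 2 * n_pairs
    units = ["pair"] * n_pairs + ["single"] * n_single
    rng.shuffle(units)

    genes: list[GeneModel] = []
    truth_rows = []
    gid = 0
    per_chrom = int(np.ceil(len(units) / cfg.n_chromosomes))
    unit_iter = iter(units)
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        pos = int(rng.integers(cfg.intergenic_min, cfg.intergenic_max))
        for _ in range(per_chrom):
            unit = next(unit_iter, None)
            if unit is None:
                break
            if unit == "pair":
                len_a = int(rng.integers(cfg.gene_len_min, cfg.gene_len_max))
                len_b = int(rng.integers(cfg.gene_len_min, cfg.gene_len_max))
                d = int(np.exp(rng.uniform(np.log(cfg.divergent_dist_min),
                                           np.log(cfg.divergent_dist_max))))
                ga = _make_gene(f"GENE{gid:05d}", chrom, "-", pos, len_a,
                                int(rng.integers(1, 4)), rng)
                gb = _make_gene(f"GENE{gid + 1:05d}", chrom, "+",
                                pos + len_a + d, len_b,
                                int(rng.integers(1, 4)), rng)
                gid += 2
                genes += [ga, gb]
                truth_rows.append((ga.gene_id, True, gb.gene_id, d))
                truth_rows.append((gb.gene_id, True, ga.gene_id, d))
                pos = gb.end
            else:
                length = int(rng.integers(cfg.gene_len_min, cfg.gene_len_max))
                g = _make_gene(f"GENE{gid:05d}", chrom,
                               "+" if rng.random() < 0.5 else "-",
                               pos, length, int(rng.integers(1, 4)), rng)
                gid += 1
                genes.append(g)
                truth_rows.append((g.gene_id, False, None, np.inf))
                pos = g.end
            pos += int(np.exp(rng.uniform(np.log(cfg.intergenic_min),
                                          np.log(cfg.intergenic_max))))

    truth = pd.DataFrame(truth_rows, columns=["gene_id", "is_divergent",
                                              "partner_id", "distance"])
    truth = truth.set_index("gene_id", drop=False)

    # planted per-gene quantities
    m = len(truth)
    expr = np.exp(rng.normal(cfg.expression_mu, cfg.expression_sigma, m))
    expr *= cfg.depth / expr.sum()
    truth["true_expression"] = expr
    truth["true_TR"] = np.exp(rng.normal(cfg.tr_mu, cfg.tr_sigma, m))
    truth["true_intron_ratio"] = np.exp(
        rng.normal(cfg.intron_ratio_mu, cfg.intron_ratio_sigma, m))
    truth["has_antisense_signal"] = (
        truth["is_divergent"].to_numpy()
        & (rng.random(m) < cfg.antisense_fraction_at_divergent))
    hi = expr >= np.quantile(expr, cfg.target_expression_quantile)
    truth["high_expressed"] = hi
    truth["is_target"] = truth["is_divergent"].to_numpy() & hi
    fc = np.zeros(m)
    targets = truth["is_target"].to_numpy()
    fc[targets] = rng.normal(cfg.kd_log2fc_mean, cfg.kd_log2fc_sigma,
                             int(targets.sum()))
    truth["true_log2FC"] = fc
    chrom_of = {g.gene_id: g.chrom for g in genes}
    truth["chrom"] = truth["gene_id"].map(chrom_of)
    return genes, truth.reset_index(drop=True)


def chromosome_lengths(genes) -> dict[str, int]:
    """Auto-sized chromosome lengths: 3x the gene footprint per chromosome
    (never shorter than the last gene end plus a margin)."""
    footprint: dict[str, int] = {}
    last_end: dict[str, int] = {}
    for g in genes:
        footprint[g.chrom] = footprint.get(g.chrom, 0) + g.length
        last_end[g.chrom] = max(last_end.get(g.chrom, 0), g.end)
    return {c: max(3 * footprint[c], last_end[c] + 10_000) for c in footprint}


# ---------------------------------------------------------------------------
# coverage + counts
# ---------------------------------------------------------------------------

def simulate_coverage(genes, truth: pd.DataFrame, cfg: SimConfig,
                      condition: str = "control",
                      rng: np.random.Generator | None = None,
                      acfg: AnalysisConfig = DEFAULT_CONFIG,
                      make_fragments: bool = True) -> dict:
    """Simulate one condition: stranded coverage plus exon/intron counts.

    Per gene, per replicate: exon reads ~ Poisson(expression x condition
    effect); intron reads ~ Poisson matched to the planted intron/exon
    coverage ratio; a fraction TR/(1+TR) of sense reads starts in the
    promoter-proximal window [TSS, TSS + pausing_window) to realize the
    planted travelling ratio, the rest uniformly over the gene body.  Genes
    flagged ``has_antisense_signal`` additionally emit >= 1 opposite-strand
    read in the ``antisense_window`` bp upstream of the TSS.  Pooled
    fragments build the '+'/'-' coverage tracks.

    Returns dict with keys ``fragments`` (DataFrame), ``coverage``
    ({'+': CoverageTrack, '-': CoverageTrack}), ``exon_counts`` /
    ``intron_counts`` (genes x replicates) and ``feature_lengths``.
    ``make_fragments=False`` skips read placement (counts only), for
    analyses that never touch coverage.
    """
    if condition not in ("control", "knockdown"):
        raise ValueError("condition must be 'control' or 'knockdown'")
    rng = rng or np.random.default_rng(cfg.seed + (1 if condition == "knockdown" else 0))
    truth = truth.set_index("gene_id", drop=False)
    gene_by_id = {g.gene_id: g for g in genes}
    chrom_len = chromosome_lengths(genes)

    intron_cols = []
    chunks: list[tuple[str, str, np.ndarray, np.ndarray]] = []  # chrom, strand, starts, ends
    flen_rows = []
    L = cfg.read_length

    effect = (2.0 ** truth["true_log2FC"].to_numpy()
              if condition == "knockdown" else np.ones(len(truth)))
    lam_exon = truth["true_expression"].to_numpy() * effect
    exon_mat = rng.poisson(lam_exon[:, None], size=(len(truth), cfg.n_replicates))
    pooled_reads = exon_mat.sum(axis=1)
    true_tr = truth["true_TR"].to_numpy()
    true_ratio = truth["true_intron_ratio"].to_numpy()
    is_target = truth["is_target"].to_numpy()
    has_antisense = truth["has_antisense_signal"].to_numpy()

    for i, gid in enumerate(truth["gene_id"]):
        gene = gene_by_id[gid]
        exon_len = sum(e - s for s, e in gene.exon_union())
        intron_len = max(gene.length - exon_len, 0)
        flen_rows.append((gid, exon_len, intron_len))
        ratio = float(true_ratio[i])
        if condition == "knockdown" and is_target[i]:
            ratio *= 2.0 ** cfg.kd_retention_log2
        lam_intron = (lam_exon[i] * ratio * intron_len / exon_len
                      if intron_len > 0 else 0.0)
        intron_cols.append(rng.poisson(lam_intron, size=cfg.n_replicates))

        if not make_fragments:
            continue
        # fragment placement (pooled over replicates) realizing the TR
        n_reads = int(pooled_reads[i])
        if n_reads > 0:
            w = acfg.pausing_window
            p_prom = true_tr[i] / (1.0 + true_tr[i])
            n_prom = int(rng.binomial(n_reads, p_prom))
            if gene.strand == "+":
                prom_lo, prom_hi = gene.start, gene.start + w
                body_lo, body_hi = gene.start + w, gene.end
            else:
                prom_lo, prom_hi = gene.end - w, gene.end
                body_lo, body_hi = gene.start, gene.end - w
            starts = np.concatenate([
                rng.integers(prom_lo, max(prom_hi - L, prom_lo + 1), n_prom),
                rng.integers(body_lo, max(body_hi - L, body_lo + 1),
                             n_reads - n_prom)])
            chunks.append((gene.chrom, gene.strand, starts, starts + L))

        if has_antisense[i]:
            n_as = 1 + int(rng.poisson(cfg.antisense_rate * lam_exon[i]))
            t = gene.tss
            aw = acfg.antisense_window
            if gene.strand == "+":
                lo, hi, strand = max(t - aw, 0), t, "-"
            else:
                lo, hi, strand = t, t + aw, "+"
            # short reads fully inside the window so calls match the truth
            rl = min(L, hi - lo)
            s = rng.integers(lo, max(hi - rl, lo + 1), n_as)
            chunks.append((gene.chrom, strand, s, s + rl))

    if chunks:
        fragments = pd.DataFrame({
            "chrom": np.concatenate([np.full(len(s), c) for c, _, s, _ in chunks]),
            "start": np.concatenate([s for _, _, s, _ in chunks]),
            "end": np.concatenate([e for _, _, _, e in chunks]),
            "strand": np.concatenate([np.full(len(s), st) for _, st, s, _ in chunks]),
        })
    else:
        fragments = pd.DataFrame(columns=["chrom", "start", "end", "strand"])
    coverage = {
        s: CoverageTrack.from_fragments(fragments, chrom_len, strand=s)
        for s in ("+", "-")} if make_fragments else {}
    rep_names = [f"{condition}_{r + 1}" for r in range(cfg.n_replicates)]
    exon_counts = pd.DataFrame(exon_mat, index=truth["gene_id"],
                               columns=rep_names)
    intron_counts = pd.DataFrame(np.vstack(intron_cols),
                                 index=truth["gene_id"], columns=rep_names)
    feature_lengths = (pd.DataFrame(flen_rows, columns=["gene_id", "exon_length",
                                                        "intron_length"])
                       .set_index("gene_id"))
    return {"fragments": fragments, "coverage": coverage,
            "exon_counts": exon_counts, "intron_counts": intron_counts,
            "feature_lengths": feature_lengths, "condition": condition}


# ---------------------------------------------------------------------------
# simple DE table (stand-in for an external DE fit)
# ---------------------------------------------------------------------------

def simulate_de_table(exon_counts_ctrl: pd.DataFrame,
                      exon_counts_kd: pd.DataFrame,
                      pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene log2FC and adjusted p-values from the two count matrices.

    A deliberately simple DE summary: log2 fold change of size-factor
    normalized mean counts (with a pseudocount), an exact binomial test of
    the knock-down read share against its expected share under no change,
    and Benjamini-Hochberg adjustment.  It is a stand-in for an external
    differential-expression fit, not a reimplementation of one.
    """
    from .ratios import size_factors

    joint = pd.concat([exon_counts_ctrl, exon_counts_kd], axis=1)
    factors = size_factors(joint)
    f_ctrl = factors[exon_counts_ctrl.columns]
    f_kd = factors[exon_counts_kd.columns]
    norm_ctrl = exon_counts_ctrl.div(f_ctrl, axis=1)
    norm_kd = exon_counts_kd.div(f_kd, axis=1)
    m_ctrl = norm_ctrl.mean(axis=1)
    m_kd = norm_kd.mean(axis=1)
    log2fc = np.log2((m_kd + pseudocount) / (m_ctrl + pseudocount))

    x = exon_counts_kd.sum(axis=1).to_numpy(dtype=np.int64)
    tot = x + exon_counts_ctrl.sum(axis=1).to_numpy(dtype=np.int64)
    p0 = float(f_kd.sum() / factors.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        lo = sps.binom.cdf(x, tot, p0)
        hi = sps.binom.sf(x - 1, tot, p0)
    pvals = np.minimum(2.0 * np.minimum(lo, hi), 1.0)
    pvals[tot == 0] = 1.0
    padj = sps.false_discovery_control(pvals, method="bh")
    return pd.DataFrame({
        "gene_id": exon_counts_ctrl.index,
        "mean_expression": (m_ctrl + m_kd).to_numpy() / 2.0,
        "log2FC": log2fc.to_numpy(),
        "pvalue": pvals,
        "padj": padj,
    }).reset_index(drop=True)
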