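import numpy as np
import pytest

from bipair import (GeneModel, SimConfig, TranscriptModel, generate_annotation,
                    simulate_coverage, simulate_de_table)


def make_gene(gene_id, chrom, strand, start, end, exons=None, tx_id=None):
    """Single-transcript gene; exons default to the whole span."""
    tx = TranscriptModel(transcript_id=tx_id or f"{gene_id}.t1",
                         exons=exons or [(start, end)])
    return GeneModel(gene_id=gene_id, gene_name=gene_id, chrom=chrom,
                     strand=strand, start=start, end=end,
                     biotype="protein_coding", transcripts=[tx])


def random_genes(rng, n_per_chrom=30, n_chrom=2, chrom_size=200_000):
    """Random non-degenerate genes for oracle comparisons (may overlap)."""
    genes = []
    gid = 0
    for ci in range(n_chrom):
        starts = rng.integers(0, chrom_size - 5000, size=n_per_chrom)
        for s in starts:
            length = int(rng.integers(500, 4000))
            genes.append(make_gene(f"R{gid:04d}", f"chr{ci + 1}",
                                   "+" if rng.random() < 0.5 else "-",
                                   int(s), int(s) + length))
            gid += 1
    return genes


@pytest.fixture(scope="session")
def sim_study():
    """One small synthetic study shared by read-only tests."""
    cfg = SimConfig(n_genes=400, depth=200_000.0, seed=7)
    genes, truth = generate_annotation(cfg)
    ctrl = simulate_coverage(genes, truth, cfg, "control")
    kd = simulate_coverage(genes, truth, cfg, "knockdown")
    de = simulate_de_table(ctrl["exon_counts"], kd["exon_counts"])
    return {"cfg": cfg, "genes": genes, "truth": truth,
            "control": ctrl, "knockdown": kd, "de": de}
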