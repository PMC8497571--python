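"""Nearest-neighbour gene-pair annotation and bidirectional-promoter calling.

For every gene the four direction x orientation categories are resolved
relative to the gene's own strand:

* ``upstream_antisense``  — head-to-head neighbour 5' of the gene on the
  opposite strand (the divergent / bidirectional-promoter configuration),
* ``upstream_sense``      — tandem neighbour 5' on the same strand,
* ``downstream_antisense``— tail-to-tail neighbour 3' on the opposite strand,
* ``downstream_sense``    — tandem neighbour 3' on the same strand.

Distance is the genomic gap between gene spans; overlapping or abutting
spans count as distance 0 and are retained.  Which side a neighbour lies on
is decided by span midpoints, which keeps the classification invariant
under mirroring all coordinates and strands.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel
from .config import AnalysisConfig, DEFAULT_CONFIG
from .coverage import CoverageTrack

CATEGORIES = ("upstream_antisense", "upstream_sense",
              "downstream_antisense", "downstream_sense")


def _category(focal_strand: str, neighbour_strand: str, genomic_left: bool) -> str:
    upstream = genomic_left if focal_strand == "+" else not genomic_left
    sense = focal_strand == neighbour_strand
    return (("upstream_" if upstream else "downstream_")
            + ("sense" if sense else "antisense"))


def annotate_pairs(genes: Sequence[GeneModel],
                   cfg: AnalysisConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Nearest neighbour per gene in each of the four pair categories.

    Returns one row per gene with, per category, the neighbour id (or None),
    the gap distance in bp (inf when no neighbour exists) and a
    ``within_threshold`` flag (distance < ``cfg.pair_max_dist``).
    """
    rows = {g.gene_id: {"gene_id": g.gene_id} for g in genes}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    for chrom_genes in by_chrom.values():
        n = len(chrom_genes)
        starts = np.array([g.start for g in chrom_genes])
        ends = np.array([g.end for g in chrom_genes])
        mids = starts + ends  # 2x midpoint, exact in integers
        strands = np.array([g.strand for g in chrom_genes])
        ids = np.array([g.gene_id for g in chrom_genes])
        id_rank = np.argsort(np.argsort(ids, kind="mergesort"), kind="mergesort")
        for i, focal in enumerate(chrom_genes):
            gap = np.maximum(starts - ends[i], starts[i] - ends)
            np.maximum(gap, 0, out=gap)
            left = (mids < mids[i]) | ((mids == mids[i]) & (id_rank < id_rank[i]))
            self_mask = np.arange(n) == i
            row = rows[focal.gene_id]
            for cat in CATEGORIES:
                up = cat.startswith("upstream")
                sense = cat.endswith("_sense")
                genomic_left = up if focal.strand == "+" else not up
                mask = (~self_mask
                        & (left == genomic_left)
                        & ((strands == focal.strand) == sense))
                if not mask.any():
                    row[f"{cat}_id"] = None
                    row[f"{cat}_dist"] = math.inf
                else:
                    idx = np.flatnonzero(mask)
                    best = idx[np.lexsort((id_rank[idx], gap[idx]))[0]]
                    row[f"{cat}_id"] = ids[best]
                    row[f"{cat}_dist"] = float(gap[best])
                row[f"{cat}_within"] = row[f"{cat}_dist"] < cfg.pair_max_dist

    cols = ["gene_id"]
    for cat in CATEGORIES:
        cols += [f"{cat}_id", f"{cat}_dist", f"{cat}_within"]
    df = pd.DataFrame([rows[g.gene_id] for g in genes], columns=cols)
    return df


def find_neighbor(gene: GeneModel, direction: str, orientation: str,
                  genes: Sequence[GeneModel]) -> tuple[str | None, float]:
    """Nearest qualifying neighbour of ``gene`` in one category.

    ``direction`` in {upstream, downstream}, ``orientation`` in
    {sense, antisense}, both relative to the focal gene's strand.
    Returns (gene_id or None, gap distance; inf when none exists).
    """
    if direction not in ("upstream", "downstream"):
        raise ValueError(f"bad direction {direction!r}")
    if orientation not in ("sense", "antisense"):
        raise ValueError(f"bad orientation {orientation!r}")
    cat = f"{direction}_{orientation}"
    pairs = annotate_pairs([g for g in genes if g.chrom == gene.chrom]
                           if gene in genes else list(genes) + [gene])
    row = pairs.set_index("gene_id").loc[gene.gene_id]
    return row[f"{cat}_id"], row[f"{cat}_dist"]


def pair_frequencies(pairs: pd.DataFrame,
                     gene_set: Sequence[str] | None = None) -> pd.Series:
    """Fraction of genes with a within-threshold neighbour, per category.

    ``gene_set`` restricts to a subset of gene ids (e.g. a DE class); the
    default is all annotated genes.
    """
    sub = pairs if gene_set is None else pairs[pairs.gene_id.isin(set(gene_set))]
    if len(sub) == 0:
        raise ValueError("empty gene set")
    return pd.Series({cat: float(sub[f"{cat}_within"].mean())
                      for cat in CATEGORIES})


# ---------------------------------------------------------------------------
# bidirectional-promoter calls from opposite-strand initiation signal
# ---------------------------------------------------------------------------

def _antisense_window(gene: GeneModel, window: int,
                      centered: bool) -> tuple[int, int, str]:
    """Window on the strand opposite the gene where divergent initiation occurs.

    Default: the ``window`` bp immediately upstream of the focal TSS (the
    region an antisense transcript initiates into).  ``centered`` switches to
    a +/- window around the TSS for sensitivity analysis.
    """
    t = gene.tss
    opposite = "-" if gene.strand == "+" else "+"
    if centered:
        return max(t - window, 0), t + window, opposite
    if gene.strand == "+":
        return max(t - window, 0), t, opposite
    return t, t + window, opposite


def call_bidirectional(genes: Sequence[GeneModel],
                       signal,
                       cfg: AnalysisConfig = DEFAULT_CONFIG,
                       centered: bool = False,
                       min_coverage: float = 0.0) -> pd.DataFrame:
    """Flag genes with opposite-strand initiation signal near their TSS.

    ``signal`` is either a stranded peak table (DataFrame with chrom, start,
    end, strand — e.g. CAGE peaks) or a dict ``{'+': CoverageTrack,
    '-': CoverageTrack}`` of antisense read coverage. A gene is called
    bidirectional when a peak overlaps — or summed opposite-strand coverage
    exceeds ``min_coverage`` within — the ``cfg.antisense_window`` bp
    upstream of its TSS on the opposite strand.
    """
    rows = []
    if isinstance(signal, pd.DataFrame):
        if "strand" not in signal.columns:
            raise ValueError("peak table must be stranded (no 'strand' column)")
        by_cs: dict[tuple[str, str], np.ndarray] = {}
        for (chrom, strand), grp in signal.groupby(["chrom", "strand"]):
            by_cs[(chrom, strand)] = grp[["start", "end"]].to_numpy()
        for gene in genes:
            lo, hi, opp = _antisense_window(gene, cfg.antisense_window, centered)
            peaks = by_cs.get((gene.chrom, opp))
            hit = bool(peaks is not None
                       and ((peaks[:, 0] < hi) & (peaks[:, 1] > lo)).any())
            rows.append((gene.gene_id, hit, "cage_peak" if hit else "",
                         cfg.antisense_window))
    elif isinstance(signal, dict):
        for track in signal.values():
            if track.strand not in ("+", "-"):
                raise ValueError("coverage tracks must be stranded")
        for gene in genes:
            lo, hi, opp = _antisense_window(gene, cfg.antisense_window, centered)
            total = float(signal[opp].window_sum(gene.chrom, lo, hi))
            hit = total > min_coverage
            rows.append((gene.gene_id, hit, "read_count" if hit else "",
                         cfg.antisense_window))
    else:
        raise TypeError("signal must be a stranded peak DataFrame or a "
                        "{'+': CoverageTrack, '-': CoverageTrack} dict")
    return pd.DataFrame(rows, columns=["gene_id", "has_opposite_tss_signal",
                                       "evidence", "window"])


# ---------------------------------------------------------------------------
# pair co-regulation
# ---------------------------------------------------------------------------

def pair_coregulation(pairs: pd.DataFrame, de_focal: pd.DataFrame,
                      de_partner: pd.DataFrame,
                      expression_floor: float = 5.0,
                      category: str = "upstream_antisense") -> dict:
    """Fold-change co-regulation of focal genes with their paired neighbours.

    ``de_focal`` holds the focal gene class (columns gene_id, log2FC);
    ``de_partner`` supplies log2FC and mean_expression for the partners.
    Pairs are stratified by partner mean expression above/below
    ``expression_floor`` and an OLS slope of partner-vs-focal log2FC is
    fitted per stratum with a two-sided t-test of slope = 0. Strata with
    fewer than 3 pairs get slope NaN and ``defined`` False.
    """
    p = pairs[["gene_id", f"{category}_id", f"{category}_within"]].copy()
    p = p[p[f"{category}_within"]]
    merged = (p.merge(de_focal[["gene_id", "log2FC"]], on="gene_id")
               .merge(de_partner[["gene_id", "log2FC", "mean_expression"]],
                      left_on=f"{category}_id", right_on="gene_id",
                      suffixes=("_focal", "_partner")))
    out = {"pairs": merged, "strata": {}}
    for name, sub in (("high", merged[merged.mean_expression >= expression_floor]),
                      ("low", merged[merged.mean_expression < expression_floor])):
        if len(sub) < 3:
            out["strata"][name] = {"n": len(sub), "slope": float("nan"),
                                   "p_value": float("nan"), "defined": False}
            continue
        fit = stats.linregress(sub["log2FC_focal"], sub["log2FC_partner"])
        out["strata"][name] = {"n": int(len(sub)), "slope": float(fit.slope),
                               "intercept": float(fit.intercept),
                               "p_value": float(fit.pvalue), "defined": True}
    return out
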