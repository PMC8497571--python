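"""Strand-aware coverage tracks, metagene matrices and Pol II pausing.

A :class:`CoverageTrack` is dense per-base signal per chromosome.  Metagene
matrices come in two layouts: *scaled-region* (fixed unscaled 5'/3' segments
with the gene body linearly rescaled to a common length) and
*reference-point* (fixed window around an anchor).  The travelling ratio
(pausing index) contrasts promoter-proximal with gene-body read signal, and
``normalize_polii`` applies a reference-gene normalization that first
subtracts the mean gene-body baseline of a set of high-expressed unchanged
genes and then scales by their mean TSS +/- 1 kb signal — making libraries
with different ChIP efficiencies directly comparable.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .config import AnalysisConfig, DEFAULT_CONFIG, MetageneLayout, RefpointLayout

logger = logging.getLogger("bipair")


class CoverageTrack:
    """Dense per-base signal over a genome, optionally strand-specific."""

    def __init__(self, chrom_lengths: dict[str, int], strand: str = ".",
                 normalization: str = "raw"):
        if strand not in ("+", "-", "."):
            raise ValueError("strand must be '+', '-' or '.'")
        self.chrom_lengths = dict(chrom_lengths)
        self.strand = strand
        self.normalization = normalization
        self.data = {c: np.zeros(l, dtype=np.float64)
                     for c, l in chrom_lengths.items()}

    # -- construction -----------------------------------------------------
    @classmethod
    def from_fragments(cls, fragments: pd.DataFrame,
                       chrom_lengths: dict[str, int],
                       extend: int = 0, strand: str = ".",
                       normalize: bool = False) -> "CoverageTrack":
        """Stamp fragment intervals onto a per-base occupancy track.

        ``fragments``: DataFrame with chrom, start, end, strand (BED
        half-open).  With ``extend`` > 0 each fragment is extended to that
        length from its 5' end (single-end ChIP convention).  ``strand``
        selects fragments of one strand ('.' keeps all).  ``normalize``
        applies per-million-per-kilobase scaling (RPKM-like) afterwards.
        Fragments running past a chromosome end are clipped with a warning.
        """
        track = cls(chrom_lengths, strand=strand)
        frags = fragments if strand == "." else fragments[fragments.strand == strand]
        n_clipped = 0
        for chrom, grp in frags.groupby("chrom", observed=True):
            if chrom not in track.data:
                logger.warning("dropping fragments on unknown chromosome %s", chrom)
                continue
            length = track.chrom_lengths[chrom]
            starts = grp["start"].to_numpy(dtype=np.int64)
            ends = grp["end"].to_numpy(dtype=np.int64)
            if extend > 0:
                fwd = grp["strand"].to_numpy() == "+"
                starts = np.where(fwd, starts, ends - extend)
                ends = np.where(fwd, starts + extend, ends)
            clip_lo, clip_hi = starts < 0, ends > length
            n_clipped += int((clip_lo | clip_hi).sum())
            starts = np.clip(starts, 0, length)
            ends = np.clip(ends, 0, length)
            delta = (np.bincount(starts, minlength=length + 1)
                     - np.bincount(ends, minlength=length + 1)).astype(np.float64)
            track.data[chrom] += np.cumsum(delta[:-1])
        if n_clipped:
            logger.warning("%d fragments clipped at chromosome boundaries", n_clipped)
        if normalize:
            # reads-per-kilobase-per-million at base resolution: c * 1e9 / N
            n_frag = max(len(frags), 1)
            for chrom in track.data:
                track.data[chrom] *= 1e9 / n_frag
            track.normalization = "RPKM-like"
        return track

    # -- access -----------------------------------------------------------
    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Signal over [start, end), zero-padded where off-chromosome."""
        out = np.zeros(end - start)
        if chrom not in self.data:
            return out
        arr = self.data[chrom]
        lo, hi = max(start, 0), min(end, len(arr))
        if hi > lo:
            out[lo - start:hi - start] = arr[lo:hi]
        return out

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        if chrom not in self.data:
            return 0.0
        arr = self.data[chrom]
        return float(arr[max(start, 0):max(min(end, len(arr)), 0)].sum())

    def total(self) -> float:
        return float(sum(a.sum() for a in self.data.values()))

    # -- bedGraph I/O ------------------------------------------------------
    def to_bedgraph(self, path: str) -> None:
        """Write run-length-encoded bedGraph (zero runs omitted)."""
        with open(path, "w") as fh:
            fh.write(f"# strand={self.strand} normalization={self.normalization}\n")
            for chrom in sorted(self.data):
                arr = self.data[chrom]
                if not len(arr):
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0.0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")

    @classmethod
    def from_bedgraph(cls, path: str, chrom_lengths: dict[str, int],
                      strand: str = ".") -> "CoverageTrack":
        track = cls(chrom_lengths, strand=strand)
        with open(path) as fh:
            for line in fh:
                if line.startswith(("#", "track", "browser")) or not line.strip():
                    if line.startswith("# strand="):
                        track.strand = line.split("strand=")[1].split()[0]
                    continue
                chrom, s, e, v = line.split("\t")
                if chrom in track.data:
                    track.data[chrom][int(s):int(e)] = float(v)
        return track


# ---------------------------------------------------------------------------
# metagene matrices
# ---------------------------------------------------------------------------

def _bin_mean(x: np.ndarray, bin_size: int) -> np.ndarray:
    """Mean of consecutive ``bin_size`` bases; a partial final bin is averaged
    over its actual width."""
    n_full = len(x) // bin_size
    out = x[:n_full * bin_size].reshape(n_full, bin_size).mean(axis=1)
    if len(x) % bin_size:
        out = np.append(out, x[n_full * bin_size:].mean())
    return out


def _rescale(x: np.ndarray, target: int) -> np.ndarray:
    """Linear resampling of a signal to ``target`` bases (constants preserved)."""
    if len(x) == target:
        return x.astype(float)
    src = np.linspace(0.0, 1.0, num=len(x))
    dst = np.linspace(0.0, 1.0, num=target)
    return np.interp(dst, src, x)


def metagene_scaled(track: CoverageTrack, genes: Sequence[GeneModel],
                    layout: MetageneLayout | None = None) -> pd.DataFrame:
    """Scaled-region metagene matrix: one row per gene, TSS on the left.

    Each row is upstream flank | unscaled 5' | body rescaled to a fixed
    length | unscaled 3' | downstream flank, binned by averaging.  Minus
    strand rows are reversed so transcription always runs left to right.
    Genes shorter than unscaled5 + unscaled3 (no body) are dropped and
    logged.  The layout is recorded in ``df.attrs['layout']``.
    """
    layout = layout or DEFAULT_CONFIG.metagene
    rows, index = [], []
    n_dropped = 0
    for gene in genes:
        if gene.length <= layout.unscaled5 + layout.unscaled3:
            n_dropped += 1
            continue
        if gene.chrom not in track.data:
            n_dropped += 1
            continue
        s, e = gene.span
        up = track.window(gene.chrom, s - layout.upstream, s)
        five = track.window(gene.chrom, s, s + layout.unscaled5)
        body = track.window(gene.chrom, s + layout.unscaled5, e - layout.unscaled3)
        three = track.window(gene.chrom, e - layout.unscaled3, e)
        down = track.window(gene.chrom, e, e + layout.downstream)
        if gene.strand == "-":
            # transcription order: flip and swap the segment roles
            up = track.window(gene.chrom, e, e + layout.upstream)[::-1]
            five = track.window(gene.chrom, e - layout.unscaled5, e)[::-1]
            body = track.window(gene.chrom, s + layout.unscaled3, e - layout.unscaled5)[::-1]
            three = track.window(gene.chrom, s, s + layout.unscaled3)[::-1]
            down = track.window(gene.chrom, s - layout.downstream, s)[::-1]
        profile = np.concatenate([up, five, _rescale(body, layout.body),
                                  three, down])
        rows.append(_bin_mean(profile, layout.bin))
        index.append(gene.gene_id)
    if n_dropped:
        logger.info("metagene_scaled: dropped %d genes (too short or off-track)",
                    n_dropped)
    df = pd.DataFrame(np.array(rows) if rows else
                      np.empty((0, layout.n_bins)), index=index)
    df.attrs["layout"] = layout
    return df


def metagene_refpoint(track: CoverageTrack,
                      anchors: pd.DataFrame,
                      layout: RefpointLayout | None = None) -> pd.DataFrame:
    """Reference-point metagene matrix around stranded anchors.

    ``anchors``: DataFrame with chrom, pos, strand, name.  The window is
    [pos - b, pos + a) in transcription orientation (minus-strand rows are
    mirrored); off-chromosome parts are zero-padded.
    """
    layout = layout or DEFAULT_CONFIG.refpoint_tss
    rows, index = [], []
    for row in anchors.itertuples(index=False):
        if row.strand == "+":
            win = track.window(row.chrom, row.pos - layout.b, row.pos + layout.a)
        elif row.strand == "-":
            win = track.window(row.chrom, row.pos - layout.a, row.pos + layout.b)[::-1]
        else:
            raise ValueError("anchors must be stranded")
        rows.append(_bin_mean(win, layout.bin))
        index.append(row.name)
    df = pd.DataFrame(np.array(rows) if rows else
                      np.empty((0, layout.n_bins)), index=index)
    df.attrs["layout"] = layout
    return df


def tss_anchors(genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Gene-level TSS anchors (5'-most transcript start per gene)."""
    return pd.DataFrame(
        [(g.chrom, g.tss, g.strand, g.gene_id) for g in genes],
        columns=["chrom", "pos", "strand", "name"])


# ---------------------------------------------------------------------------
# travelling ratio (pausing index)
# ---------------------------------------------------------------------------

def pausing_index(track: CoverageTrack, genes: Sequence[GeneModel],
                  cfg: AnalysisConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Travelling ratio per gene: promoter-proximal vs gene-body signal.

    Promoter = [TSS, TSS + pausing_window) in transcription orientation;
    body = the rest of the gene through to the TES.  Genes not longer than
    the window are excluded (logged); genes with zero body signal keep an
    infinite ratio and are flagged, not dropped.
    """
    w = cfg.pausing_window
    rows = []
    n_excluded = 0
    for gene in genes:
        if gene.length <= w:
            n_excluded += 1
            continue
        if gene.strand == "+":
            prom = track.window_sum(gene.chrom, gene.start, gene.start + w)
            body = track.window_sum(gene.chrom, gene.start + w, gene.end)
        else:
            prom = track.window_sum(gene.chrom, gene.end - w, gene.end)
            body = track.window_sum(gene.chrom, gene.start, gene.end - w)
        tr = prom / body if body > 0 else math.inf
        rows.append((gene.gene_id, prom, body, tr, body == 0))
    if n_excluded:
        logger.info("pausing_index: excluded %d genes shorter than %d bp",
                    n_excluded, w)
    return pd.DataFrame(rows, columns=["gene_id", "promoter_count",
                                       "body_count", "travelling_ratio",
                                       "body_zero"])


# ---------------------------------------------------------------------------
# reference-gene Pol II normalization
# ---------------------------------------------------------------------------

def normalize_polii(matrix: pd.DataFrame,
                    unchanged_genes: Iterable[str]) -> pd.DataFrame:
    """Normalize a scaled metagene matrix against unchanged reference genes.

    Two-step affine normalization: subtract the mean baseline signal over
    the scaled gene-body bins of the reference genes (the unscaled TSS/TES
    proximal segments are excluded by construction), then divide by their
    mean signal within TSS +/- 1 kb after subtraction.  Removes both
    background offset and ChIP-efficiency scale, so libraries become
    directly comparable.
    """
    layout: MetageneLayout = matrix.attrs["layout"]
    ref_ids = [g for g in unchanged_genes if g in matrix.index]
    if len(ref_ids) < 10:
        raise ValueError(f"need >= 10 unchanged reference genes in the matrix, "
                         f"got {len(ref_ids)}")
    ref = matrix.loc[ref_ids]
    b = layout.bin
    body_lo = (layout.upstream + layout.unscaled5) // b
    body_hi = body_lo + layout.body // b
    beta = float(ref.iloc[:, body_lo:body_hi].to_numpy().mean())
    # TSS sits at column upstream/bin; +/- 1 kb around it
    tss_col = layout.upstream // b
    k = 1000 // b
    lo, hi = max(tss_col - k, 0), tss_col + k
    mu = float((ref.iloc[:, lo:hi].to_numpy() - beta).mean())
    if mu <= 0:
        raise ValueError("degenerate reference set: TSS +/- 1 kb mean <= 0 "
                         "after baseline subtraction")
    out = (matrix - beta) / mu
    out.attrs["layout"] = layout
    out.attrs["normalization"] = {"beta": beta, "mu": mu, "n_ref": len(ref_ids)}
    return out


def select_unchanged_genes(de: pd.DataFrame, n: int,
                           cfg: AnalysisConfig = DEFAULT_CONFIG) -> list[str]:
    """High-expressed genes confidently unchanged between conditions.

    Keeps genes with |log2FC| < ``cfg.de_fc_min`` and padj >
    ``cfg.unchanged_padj_min`` (an equivalence-style filter: small point
    estimate and clearly non-significant), ranks them by mean expression
    (descending, ties broken by gene_id) and returns the top ``n``.  Fewer
    than ``n`` qualifying genes returns all of them with a warning.
    """
    ok = de[(de["log2FC"].abs() < cfg.de_fc_min)
            & (de["padj"] > cfg.unchanged_padj_min)]
    ranked = ok.sort_values(["mean_expression", "gene_id"],
                            ascending=[False, True], kind="mergesort")
    if len(ranked) < n:
        logger.warning("only %d unchanged genes qualify (requested %d)",
                       len(ranked), n)
    return ranked["gene_id"].head(n).tolist()
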