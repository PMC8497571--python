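"""Gene-model parsing and strand-aware annotation primitives.

Parses Gencode-style GTF into light-weight gene models, classifies exons by
their position within transcripts (first / internal / last), derives introns
by subtracting the exonic union from the gene span, builds promoter windows
around transcript start sites and defines putative enhancers as histone-mark
peaks clear of any promoter.

Internal coordinates are 0-based half-open everywhere; the GTF reader and
writer convert to/from the 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from gffutils.feature import feature_from_line

from .config import AnalysisConfig, DEFAULT_CONFIG

Interval = tuple[int, int]


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"GTF parse error at line {lineno}: {message}")
        self.lineno = lineno


class AnnotationValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """A transcript: an ordered (genomic order) list of non-overlapping exons."""

    transcript_id: str
    exons: list[Interval] = field(default_factory=list)

    def validate(self) -> None:
        if not self.exons:
            raise AnnotationValidationError(
                f"transcript {self.transcript_id} has no exons")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise AnnotationValidationError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{s1},{e1}) and [{s2},{e2})")
        self.exons = exons

    @property
    def span(self) -> Interval:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))


@dataclass
class GeneModel:
    """A stranded gene with its transcripts; source of TSS/TES anchors."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = ""
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', "
                f"got {self.strand!r}")
        for tx in self.transcripts:
            tx.validate()
            ts, te = tx.span
            if ts < self.start or te > self.end:
                raise AnnotationValidationError(
                    f"gene {self.gene_id}: transcript {tx.transcript_id} "
                    f"span [{ts},{te}) outside gene span "
                    f"[{self.start},{self.end})")

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def tss(self) -> int:
        """Gene-level TSS: 5'-most position in transcription orientation.

        With half-open coordinates the TSS of a minus-strand gene is its
        span end, so that [tss - w, tss) is always the w bp immediately
        upstream regardless of strand.
        """
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    def exon_union(self) -> list[Interval]:
        return merge_intervals(iv for tx in self.transcripts for iv in tx.exons)

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# interval arithmetic (half-open)
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Coalesce overlapping or abutting half-open intervals into a minimal set."""
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if e < s:
            raise ValueError(f"invalid interval [{s},{e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def subtract_intervals(span: Interval, holes: Iterable[Interval]) -> list[Interval]:
    """``span`` minus the union of ``holes``, as maximal disjoint intervals."""
    s0, e0 = span
    out: list[Interval] = []
    cursor = s0
    for hs, he in merge_intervals(holes):
        hs, he = max(hs, s0), min(he, e0)
        if he <= hs:
            continue
        if hs > cursor:
            out.append((cursor, hs))
        cursor = max(cursor, he)
    if cursor < e0:
        out.append((cursor, e0))
    return out


def intervals_overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def gap_distance(a: Interval, b: Interval) -> int:
    """Genomic gap between two spans; 0 when they overlap or abut."""
    if a[0] < b[1] and b[0] < a[1]:
        return 0
    return max(a[0], b[0]) - min(a[1], b[1])


# ---------------------------------------------------------------------------
# GTF I/O (Gencode attribute dialect)
# ---------------------------------------------------------------------------

def _attr(feature, *names: str) -> str | None:
    for name in names:
        if name in feature.attributes:
            return feature.attributes[name][0]
    return None


def parse_gtf(path: str, biotype_filter: str | None = None) -> list[GeneModel]:
    """Read a GTF file into :class:`GeneModel` objects.

    Only ``gene``, ``transcript`` and ``exon`` features are consumed; gene
    and transcript records are optional (models are grown from exon lines if
    absent). ``biotype_filter`` keeps genes whose ``gene_type`` (or
    ``gene_biotype``) matches. Output is deterministically ordered by
    (chrom, start, gene_id).
    """
    genes: dict[str, GeneModel] = {}
    tx_index: dict[str, TranscriptModel] = {}
    tx_gene: dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise GtfParseError(
                    lineno, f"expected 9 tab-separated fields, "
                    f"got {line.count(chr(9)) + 1}")
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:
                raise GtfParseError(lineno, str(exc)) from exc
            if feat.featuretype not in ("gene", "transcript", "exon"):
                continue
            gene_id = _attr(feat, "gene_id")
            if gene_id is None:
                raise GtfParseError(lineno, "missing gene_id attribute")
            start0, end0 = feat.start - 1, feat.end  # 1-based incl -> half-open
            if start0 < 0 or end0 <= start0:
                raise GtfParseError(lineno, f"bad coordinates {feat.start}..{feat.end}")
            if gene_id not in genes:
                genes[gene_id] = GeneModel(
                    gene_id=gene_id,
                    gene_name=_attr(feat, "gene_name") or gene_id,
                    chrom=feat.seqid, strand=feat.strand,
                    start=start0, end=end0,
                    biotype=_attr(feat, "gene_type", "gene_biotype") or "")
            gene = genes[gene_id]
            if feat.featuretype == "gene":
                gene.start, gene.end = start0, end0
                gene.biotype = _attr(feat, "gene_type", "gene_biotype") or gene.biotype
                gene.gene_name = _attr(feat, "gene_name") or gene.gene_name
                continue
            tx_id = _attr(feat, "transcript_id")
            if tx_id is None:
                raise GtfParseError(lineno, "missing transcript_id attribute")
            if tx_id not in tx_index:
                tx_index[tx_id] = TranscriptModel(transcript_id=tx_id)
                tx_gene[tx_id] = gene_id
                gene.transcripts.append(tx_index[tx_id])
            if feat.featuretype == "exon":
                tx_index[tx_id].exons.append((start0, end0))

    out = []
    for gene in genes.values():
        gene.transcripts = [tx for tx in gene.transcripts if tx.exons]
        if not gene.transcripts:
            continue
        # grow gene span to cover transcripts when no explicit gene record did
        lo = min(tx.span[0] for tx in gene.transcripts)
        hi = max(tx.span[1] for tx in gene.transcripts)
        gene.start, gene.end = min(gene.start, lo), max(gene.end, hi)
        gene.validate()
        if biotype_filter is None or gene.biotype == biotype_filter:
            out.append(gene)
    out.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return out


def write_gtf(genes: Sequence[GeneModel], path: str) -> None:
    """Write gene models as Gencode-style GTF (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        for gene in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = (f'gene_id "{gene.gene_id}"; gene_type "{gene.biotype}"; '
                     f'gene_name "{gene.gene_name}";')
            fh.write(f"{gene.chrom}\tbipair\tgene\t{gene.start + 1}\t{gene.end}"
                     f"\t.\t{gene.strand}\t.\t{attrs}\n")
            for tx in gene.transcripts:
                ts, te = tx.span
                tattrs = attrs + f' transcript_id "{tx.transcript_id}";'
                fh.write(f"{gene.chrom}\tbipair\ttranscript\t{ts + 1}\t{te}"
                         f"\t.\t{gene.strand}\t.\t{tattrs}\n")
                for s, e in tx.exons:
                    fh.write(f"{gene.chrom}\tbipair\texon\t{s + 1}\t{e}"
                             f"\t.\t{gene.strand}\t.\t{tattrs}\n")


# ---------------------------------------------------------------------------
# exon classification
# ---------------------------------------------------------------------------

def classify_exons(genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Label each unique exon of each gene as first / internal / last.

    Position is taken in transcription orientation per transcript; labels are
    unioned over all transcripts of the gene that contain the exon (same
    chrom/start/end). A single-exon transcript contributes both ``first`` and
    ``last``. ``exclusively_first`` marks exons labelled first and nothing
    else anywhere in the gene.

    Returns a DataFrame with one row per unique (gene_id, start, end) exon:
    columns chrom, start, end, strand, gene_id, first, internal, last,
    exclusively_first, n_transcripts (transcripts of the gene containing it).
    The total number of exon annotations (transcript-level, with repeats) is
    stored in ``df.attrs['n_exon_annotations']``.
    """
    rows: dict[tuple, dict] = {}
    n_annotations = 0
    for gene in genes:
        for tx in gene.transcripts:
            exons = sorted(tx.exons)
            if gene.strand == "-":
                ordered = exons[::-1]  # transcription order: 5' -> 3'
            else:
                ordered = exons
            k = len(ordered)
            for i, (s, e) in enumerate(ordered):
                n_annotations += 1
                labels = set()
                if i == 0:
                    labels.add("first")
                if i == k - 1:
                    labels.add("last")
                if 0 < i < k - 1:
                    labels.add("internal")
                key = (gene.gene_id, s, e)
                row = rows.setdefault(key, {
                    "chrom": gene.chrom, "start": s, "end": e,
                    "strand": gene.strand, "gene_id": gene.gene_id,
                    "first": False, "internal": False, "last": False,
                    "n_transcripts": 0})
                row["n_transcripts"] += 1
                for lab in labels:
                    row[lab] = True
    df = pd.DataFrame(list(rows.values()),
                      columns=["chrom", "start", "end", "strand", "gene_id",
                               "first", "internal", "last", "n_transcripts"])
    if not df.empty:
        df["exclusively_first"] = df["first"] & ~df["internal"] & ~df["last"]
        df = df.sort_values(["chrom", "start", "end", "gene_id"],
                            kind="mergesort").reset_index(drop=True)
    else:
        df["exclusively_first"] = pd.Series(dtype=bool)
    df.attrs["n_exon_annotations"] = n_annotations
    df.attrs["n_exclusively_first"] = int(df["exclusively_first"].sum()) if len(df) else 0
    return df


# ---------------------------------------------------------------------------
# introns, promoters, enhancers
# ---------------------------------------------------------------------------

def derive_introns(gene: GeneModel) -> list[Interval]:
    """Introns = gene span minus the union of exons of all its transcripts."""
    if not gene.transcripts:
        raise AnnotationValidationError(f"gene {gene.gene_id} has no transcripts")
    return subtract_intervals(gene.span, gene.exon_union())


def promoter_windows(genes: Sequence[GeneModel],
                     cfg: AnalysisConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Strand-aware promoter window per transcript TSS (default -900/+100 bp).

    On the minus strand the window is reflected; windows running past the
    chromosome start are clipped at 0. Returns BED-like columns
    (chrom, start, end, name, strand) with one row per transcript.
    """
    up, down = cfg.promoter_upstream, cfg.promoter_downstream
    rows = []
    for gene in genes:
        for tx in gene.transcripts:
            ts, te = tx.span
            if gene.strand == "+":
                lo, hi = ts - up, ts + down
            else:
                lo, hi = te - down, te + up
            rows.append((gene.chrom, max(lo, 0), hi,
                         f"{gene.gene_id}|{tx.transcript_id}", gene.strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])


def define_enhancers(peaks: pd.DataFrame, genes: Sequence[GeneModel],
                     cfg: AnalysisConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Putative enhancers: peaks with zero overlap against any promoter window.

    ``peaks`` needs columns chrom/start/end (BED half-open). A 1-bp overlap
    with a promoter excludes the peak. The returned frame carries a
    ``center`` column for reference-point profiling.
    """
    promoters = promoter_windows(genes, cfg)
    keep = []
    by_chrom: dict[str, list[Interval]] = {}
    for _, p in promoters.iterrows():
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    for chrom in by_chrom:
        by_chrom[chrom] = merge_intervals(by_chrom[chrom])
    for _, row in peaks.iterrows():
        ivs = by_chrom.get(row.chrom, [])
        if not any(intervals_overlap((row.start, row.end), iv) for iv in ivs):
            keep.append(row)
    out = pd.DataFrame(keep, columns=peaks.columns).reset_index(drop=True)
    out["center"] = (out["start"] + out["end"]) // 2 if len(out) else pd.Series(dtype=int)
    return out
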