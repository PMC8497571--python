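"""Analysis-wide configuration.

All windows and thresholds used throughout the pipeline live in a single
:class:`AnalysisConfig` so every stage sees one consistent set of conventions.
Coordinates are 0-based half-open internally; GTF I/O converts at the boundary
and BED/bedGraph pass through unchanged.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass(frozen=True)
class MetageneLayout:
    """Scaled-region metagene layout in base pairs.

    The gene body between the unscaled 5' and 3' segments is linearly
    rescaled to ``body`` bp; ``upstream``/``downstream`` are the flanks
    outside the gene.
    """

    upstream: int = 1000
    unscaled5: int = 1000
    body: int = 500
    unscaled3: int = 500
    downstream: int = 500
    bin: int = 10

    @property
    def total_bp(self) -> int:
        return (self.upstream + self.unscaled5 + self.body
                + self.unscaled3 + self.downstream)

    @property
    def n_bins(self) -> int:
        return self.total_bp // self.bin


@dataclass(frozen=True)
class RefpointLayout:
    """Reference-point metagene layout: ``b`` bp before to ``a`` bp after."""

    b: int = 500
    a: int = 500
    bin: int = 1

    @property
    def n_bins(self) -> int:
        return (self.b + self.a) // self.bin


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and windows for the bidirectional-pair / pausing analysis.

    Attributes
    ----------
    pausing_window : bp downstream of the TSS counted as promoter-proximal
        for the travelling ratio (promoter = [TSS, TSS+250) in transcription
        orientation).
    pair_max_dist : maximum gap (bp) between gene spans for a neighbour to
        count as a close pair.
    antisense_window : bp upstream of the TSS screened for opposite-strand
        initiation signal when calling bidirectional promoters.
    promoter_upstream / promoter_downstream : promoter window around each
        transcript TSS (-900/+100 bp), used e.g. to exclude promoters from
        enhancer definitions.
    read_extension : single-end ChIP fragments are extended to this length.
    de_fc_min / de_padj_max : |log2FC| and adjusted-p thresholds defining
        up/down regulated gene classes.
    cpm_min : mean counts-per-million floor for the intron/exon ratio.
    ratio_hi / ratio_lo : substitution values for degenerate intron/exon
        ratios (no exon counts -> ratio_hi; (nearly) no intron counts ->
        ratio_lo).
    n_resample / ci_level : number of random gene subsets and confidence
        level for the resampling null band.
    unchanged_padj_min : padj floor for the "significantly unchanged" gene
        selection used in Pol II library normalization.
    """

    pausing_window: int = 250
    pair_max_dist: int = 1000
    antisense_window: int = 100
    promoter_upstream: int = 900
    promoter_downstream: int = 100
    read_extension: int = 150
    metagene: MetageneLayout = field(default_factory=MetageneLayout)
    refpoint_tss: RefpointLayout = field(default_factory=RefpointLayout)
    refpoint_atac: RefpointLayout = field(
        default_factory=lambda: RefpointLayout(b=3000, a=3000, bin=10))
    de_fc_min: float = 0.3
    de_padj_max: float = 0.05
    unchanged_padj_min: float = 0.5
    n_unchanged: int = 199
    cpm_min: float = 20.0
    ratio_hi: float = 1.0
    ratio_lo: float = 0.001
    n_resample: int = 10000
    ci_level: float = 0.999
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pausing_window", "pair_max_dist", "antisense_window",
                     "promoter_upstream", "promoter_downstream"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie strictly in (0, 1)")
        if self.n_resample < 1:
            raise ValueError("n_resample must be >= 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if isinstance(d.get("metagene"), dict):
            d["metagene"] = MetageneLayout(**d["metagene"])
        for key in ("refpoint_tss", "refpoint_atac"):
            if isinstance(d.get(key), dict):
                d[key] = RefpointLayout(**d[key])
        return cls(**d)


DEFAULT_CONFIG = AnalysisConfig()
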