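"""Size factors and intron/exon coverage ratios.

Sequencing depth is removed with median-of-ratios size factors computed
from exonic counts only.  The intron/exon ratio per gene is mean intronic
per-base coverage divided by mean exonic per-base coverage (normalized
count / feature length); elevated values indicate intron retention.
Degenerate ratios are substituted: genes with no exon counts get
``ratio_hi`` (1), genes with (nearly) no intron counts get ``ratio_lo``
(0.001), and each substitution is flagged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig, DEFAULT_CONFIG

logger = logging.getLogger("bipair")


def size_factors(exon_counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (column).

    factor_j = median over genes g of count_gj / geomean_s(count_gs),
    using only genes with nonzero counts in every sample.
    """
    if exon_counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    mat = exon_counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene has nonzero counts in all samples")
    sub = mat[all_nonzero]
    geomean = np.exp(np.log(sub).mean(axis=1, keepdims=True))
    factors = np.median(sub / geomean, axis=0)
    return pd.Series(factors, index=exon_counts.columns, name="size_factor")


def intron_exon_ratio(exon_counts: pd.DataFrame, intron_counts: pd.DataFrame,
                      factors: pd.Series, feature_lengths: pd.DataFrame,
                      cfg: AnalysisConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Per-gene intron/exon coverage ratio with degenerate-value substitution.

    ``feature_lengths``: DataFrame indexed by gene_id with columns
    ``exon_length`` and ``intron_length`` (total bp). Counts are first
    divided by size factors; genes must pass a mean-CPM filter (exonic
    counts, > ``cfg.cpm_min``). Mean coverage = mean normalized count /
    feature length. Genes with zero exon counts take ratio 1 (flag
    ``no_exon->hi``); genes with zero intron counts or a ratio below
    ``cfg.ratio_lo`` take ratio 0.001 (flag ``low_intron->lo``). Genes with
    zero counts in both features are excluded and logged.
    """
    common = exon_counts.index.intersection(intron_counts.index)
    exon = exon_counts.loc[common].div(factors, axis=1)
    intron = intron_counts.loc[common].div(factors, axis=1)

    # CPM filter on raw exonic counts (mean across samples)
    cpm = exon_counts.loc[common] / exon_counts.sum(axis=0) * 1e6
    passing = cpm.mean(axis=1) > cfg.cpm_min

    rows = []
    n_excluded = 0
    for gene in common[passing]:
        ex_mean = float(exon.loc[gene].mean())
        in_mean = float(intron.loc[gene].mean())
        ex_len = float(feature_lengths.loc[gene, "exon_length"])
        in_len = float(feature_lengths.loc[gene, "intron_length"])
        if ex_len <= 0 or in_len <= 0:
            n_excluded += 1
            continue
        if ex_mean == 0 and in_mean == 0:
            n_excluded += 1
            continue
        ex_cov = ex_mean / ex_len
        in_cov = in_mean / in_len
        if ex_cov == 0:
            ratio, flag = cfg.ratio_hi, "no_exon->hi"
        else:
            ratio = in_cov / ex_cov
            if in_mean == 0 or ratio < cfg.ratio_lo:
                ratio, flag = cfg.ratio_lo, "low_intron->lo"
            else:
                flag = "none"
        rows.append((gene, ex_cov, in_cov, ratio, flag))
    if n_excluded:
        logger.info("intron_exon_ratio: excluded %d genes (zero counts or "
                    "missing feature lengths)", n_excluded)
    return pd.DataFrame(rows, columns=["gene_id", "mean_exon_coverage",
                                       "mean_intron_coverage", "ratio",
                                       "degenerate_flag"])


def ratio_vs_fc(ratios_ctrl: pd.DataFrame, ratios_kd: pd.DataFrame,
                de: pd.DataFrame) -> dict:
    """Correlate expression change with intron/exon-ratio change per gene.

    Joins the control and knock-down ratio tables with the DE table on
    gene_id, computes log2(ratio_kd / ratio_ctrl) and reports the Spearman
    rank correlation with log2FC.  Fewer than 10 shared genes warns; a
    constant ratio-change vector leaves the correlation undefined (flagged).
    """
    merged = (ratios_ctrl[["gene_id", "ratio"]]
              .merge(ratios_kd[["gene_id", "ratio"]], on="gene_id",
                     suffixes=("_ctrl", "_kd"))
              .merge(de[["gene_id", "log2FC"]], on="gene_id"))
    if len(merged) < 10:
        logger.warning("ratio_vs_fc: only %d shared genes", len(merged))
    merged["log2_ratio_change"] = np.log2(merged["ratio_kd"] / merged["ratio_ctrl"])
    if merged["log2_ratio_change"].nunique() <= 1 or len(merged) < 2:
        return {"table": merged, "spearman_rho": float("nan"),
                "p_value": float("nan"), "defined": False}
    rho, p = stats.spearmanr(merged["log2FC"], merged["log2_ratio_change"])
    return {"table": merged, "spearman_rho": float(rho), "p_value": float(p),
            "defined": True}
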