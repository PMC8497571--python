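"""DE classification, enrichment tests, resampling null bands and ECDFs.

Genes are classified up/down/unchanged from an input differential-expression
table with strict thresholds (|log2FC| > 0.3 and padj < 0.05 by default).
Fold enrichment of a pair category within a DE class over the gene universe
is tested with a two-sided Fisher's exact test.  Metagene profiles of gene
classes are compared against a null band built from many random gene
subsets of the same size (nearest-rank percentiles, e.g. the 99.9% CI of
10,000 draws).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import AnalysisConfig, DEFAULT_CONFIG


# ---------------------------------------------------------------------------
# DE classification
# ---------------------------------------------------------------------------

def classify_de(de: pd.DataFrame,
                cfg: AnalysisConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Attach an up/down/unchanged class to a DE table.

    up: log2FC > de_fc_min and padj < de_padj_max; down mirrored; everything
    else (including missing padj, which is logged as unclassified)
    unchanged.  Strict inequalities throughout.  Duplicate gene ids raise.
    """
    if de["gene_id"].duplicated().any():
        dupes = de.loc[de["gene_id"].duplicated(), "gene_id"].head().tolist()
        raise ValueError(f"duplicate gene ids in DE table, e.g. {dupes}")
    bad = de["padj"].dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ValueError("padj values outside [0, 1]")
    out = de.copy()
    sig = out["padj"].notna() & (out["padj"] < cfg.de_padj_max)
    out["de_class"] = "unchanged"
    out.loc[sig & (out["log2FC"] > cfg.de_fc_min), "de_class"] = "up"
    out.loc[sig & (out["log2FC"] < -cfg.de_fc_min), "de_class"] = "down"
    return out


def de_class_counts(de: pd.DataFrame) -> pd.Series:
    return de["de_class"].value_counts()


# ---------------------------------------------------------------------------
# fold enrichment (Fisher's exact test)
# ---------------------------------------------------------------------------

def fold_enrichment(pairs: pd.DataFrame, class_genes, category: str,
                    universe=None) -> dict:
    """Enrichment of a pair category in a gene class vs the universe.

    fold = fraction of class genes with a within-threshold neighbour in
    ``category`` divided by the same fraction over the universe (default:
    all genes in ``pairs``).  A two-sided Fisher's exact test is run on the
    2x2 table (in class / not in class) x (has neighbour / has not); note
    p-values are per-category — no multiple-testing correction is applied
    across categories.
    """
    col = f"{category}_within"
    if col not in pairs.columns:
        raise ValueError(f"unknown category {category!r}")
    universe_ids = (set(pairs["gene_id"]) if universe is None else set(universe))
    class_ids = set(class_genes) & universe_ids
    if not class_ids:
        raise ValueError("empty gene class")
    uni = pairs[pairs["gene_id"].isin(universe_ids)]
    in_class = uni["gene_id"].isin(class_ids)
    has = uni[col].astype(bool)
    a = int((in_class & has).sum())
    b = int((in_class & ~has).sum())
    c = int((~in_class & has).sum())
    d = int((~in_class & ~has).sum())
    frac_class = a / (a + b)
    frac_universe = (a + c) / max(a + b + c + d, 1)
    fold = frac_class / frac_universe if frac_universe > 0 else float("inf")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {"fold": float(fold), "table": ((a, b), (c, d)),
            "p_value": float(p), "frac_class": frac_class,
            "frac_universe": frac_universe, "category": category,
            "note": "p-value is per-category (no cross-category correction)"}


# ---------------------------------------------------------------------------
# resampling null band
# ---------------------------------------------------------------------------

def _nearest_rank(sorted_draws: np.ndarray, q: float) -> np.ndarray:
    """Nearest-rank percentile per column of a (draws x columns) sorted array."""
    n = sorted_draws.shape[0]
    rank = min(max(int(np.ceil(q * n)), 1), n) - 1
    return sorted_draws[rank]


def resample_null_band(matrix: pd.DataFrame, subset_size: int,
                       cfg: AnalysisConfig = DEFAULT_CONFIG,
                       seed: int | None = None) -> dict:
    """Per-column confidence band of mean profiles of random gene subsets.

    Draws ``cfg.n_resample`` subsets of ``subset_size`` rows without
    replacement, takes each subset's per-column mean profile and returns the
    nearest-rank [(1-ci)/2, 1-(1-ci)/2] percentile band per column, bit
    reproducible for a fixed seed.
    """
    if subset_size <= 0:
        raise ValueError("subset_size must be positive")
    n = len(matrix)
    if subset_size > n:
        raise ValueError(f"subset_size {subset_size} > matrix rows {n}")
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    values = matrix.to_numpy(dtype=float)
    draws = np.empty((cfg.n_resample, values.shape[1]))
    for i in range(cfg.n_resample):
        idx = rng.choice(n, size=subset_size, replace=False)
        draws[i] = values[idx].mean(axis=0)
    draws.sort(axis=0)
    alpha = 1.0 - cfg.ci_level
    lower = _nearest_rank(draws, alpha / 2)
    upper = _nearest_rank(draws, 1.0 - alpha / 2)
    return {"lower": lower, "upper": upper, "n_iter": cfg.n_resample,
            "ci_level": cfg.ci_level, "subset_size": subset_size,
            "seed": int(cfg.rng_seed if seed is None else seed)}


def band_exclusion(band: dict, profile: np.ndarray) -> dict:
    """Flag the columns of an observed profile outside the null band."""
    outside = (profile < band["lower"]) | (profile > band["upper"])
    return {"outside": outside, "fraction_outside": float(outside.mean())}


# ---------------------------------------------------------------------------
# ECDFs and set shares
# ---------------------------------------------------------------------------

def expression_ecdf(counts: pd.Series, gene_sets: dict[str, list],
                    log_scale: bool = True, pseudocount: float = 1.0) -> dict:
    """Cumulative relative frequency of read counts per gene set.

    Returns per-set sorted (x, ecdf) arrays (on log10 counts when
    ``log_scale``) and pairwise two-sample Kolmogorov-Smirnov D statistics.
    """
    curves = {}
    samples = {}
    for name, ids in gene_sets.items():
        vals = counts.loc[[g for g in ids if g in counts.index]].to_numpy(float)
        if len(vals) == 0:
            raise ValueError(f"gene set {name!r} is empty")
        x = np.log10(vals + pseudocount) if log_scale else vals
        x = np.sort(x)
        curves[name] = (x, np.arange(1, len(x) + 1) / len(x))
        samples[name] = x
    names = list(gene_sets)
    ks = {}
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            d, p = sps.ks_2samp(samples[na], samples[nb])
            ks[(na, nb)] = {"D": float(d), "p_value": float(p)}
    return {"curves": curves, "ks": ks}


def category_share(class_genes, tagged_genes) -> float:
    """|class ∩ tag| / |class| — e.g. the histone-gene share of a DE class."""
    class_set = set(class_genes)
    if not class_set:
        raise ValueError("empty gene class")
    return len(class_set & set(tagged_genes)) / len(class_set)
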