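"""Differential expression between cell groups.

Two tests are provided. The two-class test is a resampled Wilcoxon rank-sum
statistic in the SAMseq style: raw counts (spike-ins excluded) are repeatedly
Poisson-downsampled to the minimum library depth so that sequencing-depth
differences cannot masquerade as expression differences, the standardized
rank-sum statistic is averaged over resamples, and q-values come from a SAM
permutation scheme (median permuted call count over observed call count at
each cut point, monotonized). The per-cluster marker test is a binomial
counting statistic: each gene's share of the target cluster's reads is
compared with its share in the remaining cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionTable

__all__ = [
    "DEParams",
    "rank_columns",
    "samseq_two_class",
    "binomial_cluster_markers",
    "volcano_table",
    "significant_genes",
]


@dataclass
class DEParams:
    n_resamples: int = 20
    n_permutations: int = 100
    fdr_threshold: float = 0.05
    fold_change_min: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if self.n_permutations < 10:
            raise ValueError("n_permutations must be >= 10")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must lie in (0, 1)")


def rank_columns(m: np.ndarray) -> np.ndarray:
    """Column-wise ranks of a matrix, ties receiving the mean of tied ranks.

    Each column is replaced by ranks 1..n_rows; this is the rank kernel the
    resampled Wilcoxon statistic is built on.
    """
    m = np.asarray(m, dtype=float)
    if m.size == 0:
        raise ValueError("empty matrix")
    if not np.isfinite(m).all():
        raise ValueError("matrix contains non-finite entries")
    return scipy.stats.rankdata(m, axis=0, method="average")


def _wilcoxon_stats(ranks: np.ndarray, group1: np.ndarray) -> np.ndarray:
    """Standardized rank-sum statistics per gene.

    ``ranks`` is genes x cells with within-gene ranks; the statistic is
    (T - n1 (n+1)/2) / sqrt(n0 n1 (n+1) / 12) with T the rank sum of group 1,
    positive when expression is higher in group 1.
    """
    n = ranks.shape[1]
    n1 = int(group1.sum())
    n0 = n - n1
    T = ranks[:, group1].sum(axis=1)
    mu = n1 * (n + 1) / 2.0
    sigma = np.sqrt(n0 * n1 * (n + 1) / 12.0)
    return (T - mu) / sigma


def samseq_two_class(
    raw: ExpressionTable, groups: np.ndarray, params: DEParams | None = None
) -> pd.DataFrame:
    """Resampled-Wilcoxon two-class differential expression on raw counts.

    ``groups`` is a binary label per cell (0/1); positive statistic means
    higher expression in group 1. Returns a per-gene table with columns
    ``statistic``, ``mean_group0``, ``mean_group1`` (depth-equalized means),
    ``log2_fc`` (pseudocount 0.5), ``q`` and ``direction``.
    """
    params = params or DEParams()
    groups = np.asarray(groups).astype(int)
    if set(np.unique(groups)) - {0, 1}:
        raise ValueError("groups must be binary 0/1 labels")
    if (groups == 1).sum() == 0 or (groups == 0).sum() == 0:
        raise ValueError("both groups must be non-empty")
    bio = raw.biological()
    counts = bio.counts
    depths = counts.sum(axis=0)
    if (depths <= 0).any():
        raise ValueError("cells with zero depth")
    rate = depths.min() / depths

    rng = np.random.default_rng(params.seed)
    n_genes, n_cells = counts.shape
    rank_stack = np.empty((params.n_resamples, n_genes, n_cells))
    scaled_sum = np.zeros_like(counts)
    for r in range(params.n_resamples):
        # Poisson thinning to the common minimum depth; cells already at the
        # minimum are left untouched, so equal depths reduce to the classical
        # rank-sum statistic
        resampled = np.where(
            np.isclose(rate, 1.0)[None, :], counts, rng.poisson(counts * rate[None, :])
        )
        # rank within each gene across cells: rank_columns on the transpose
        rank_stack[r] = rank_columns(resampled.T).T
        scaled_sum += resampled
    g1 = groups == 1
    stats = np.mean([_wilcoxon_stats(rank_stack[r], g1) for r in range(params.n_resamples)], axis=0)

    perm_stats = np.empty((params.n_permutations, n_genes))
    for p in range(params.n_permutations):
        perm = rng.permutation(groups) == 1
        perm_stats[p] = np.mean(
            [_wilcoxon_stats(rank_stack[r], perm) for r in range(params.n_resamples)], axis=0
        )

    q = _sam_qvalues(stats, perm_stats)

    scaled = scaled_sum / params.n_resamples
    m0 = scaled[:, ~g1].mean(axis=1)
    m1 = scaled[:, g1].mean(axis=1)
    log2_fc = np.log2((m1 + 0.5) / (m0 + 0.5))
    allzero = counts.sum(axis=1) == 0
    stats[allzero] = 0.0
    q[allzero] = 1.0
    direction = np.where(stats >= 0, "up", "down")
    return pd.DataFrame(
        {
            "statistic": stats,
            "mean_group0": m0,
            "mean_group1": m1,
            "log2_fc": log2_fc,
            "q": q,
            "direction": direction,
        },
        index=bio.gene_ids,
    )


def _sam_qvalues(
    stats: np.ndarray, perm_stats: np.ndarray, center: str = "mean"
) -> np.ndarray:
    """SAM-style q-values from observed and permuted statistics.

    For the cut point |d_i|, FDR = expected (mean over permutations) number
    of permuted |statistics| >= |d_i|, divided by the number of observed
    |statistics| >= |d_i|; q-values are then monotonized so a larger
    |statistic| never has a larger q. ``center="median"`` uses the median
    permuted call count instead; the median degenerates to zero at extreme
    cut points (where the count distribution sits on {0, 1}), so the
    expectation is the default.
    """
    a = np.abs(stats)
    ap = np.abs(perm_stats)
    order = np.argsort(-a, kind="stable")
    q = np.empty_like(a)
    sorted_a = a[order]
    # observed calls at cut |d_(i)| is i+1 (ties share the larger count)
    obs = np.searchsorted(-sorted_a, -sorted_a, side="right")
    perm_sorted = np.sort(ap, axis=1)
    counts = ap.shape[1] - np.apply_along_axis(
        np.searchsorted, 1, perm_sorted, sorted_a, side="left"
    )
    false_calls = np.mean(counts, axis=0) if center == "mean" else np.median(counts, axis=0)
    q_sorted = np.clip(false_calls / np.maximum(obs, 1), 0.0, 1.0)
    q_sorted = np.maximum.accumulate(q_sorted)  # monotone in decreasing |d|
    q[order] = q_sorted
    return q


def binomial_cluster_markers(
    raw: ExpressionTable,
    labels: np.ndarray,
    target_cluster: int,
    params: DEParams | None = None,
) -> pd.DataFrame:
    """Binomial marker test of one cluster against all remaining cells.

    With T the target cluster's total read count and p0 each gene's smoothed
    share of the remaining cells' reads, the gene's target count x is tested
    against Binomial(T, p0); the two-sided p-value is
    2 * min(upper tail, lower tail, 0.5). Fold change is (x/T) / p0 and
    q-values are Benjamini-Hochberg.
    """
    params = params or DEParams()
    labels = np.asarray(labels)
    in_target = labels == target_cluster
    if not in_target.any():
        raise ValueError(f"target cluster {target_cluster} is empty")
    if in_target.all():
        raise ValueError("target cluster must not contain every cell")
    bio = raw.biological()
    x = bio.counts[:, in_target].sum(axis=1)
    rest = bio.counts[:, ~in_target].sum(axis=1)
    T = x.sum()
    if T <= 0:
        raise ValueError("target cluster has zero total counts")
    p0 = (rest + 0.5) / (rest.sum() + 0.5)
    upper = scipy.stats.binom.sf(x - 1, int(T), p0)
    lower = scipy.stats.binom.cdf(x, int(T), p0)
    p = 2.0 * np.minimum(np.minimum(upper, lower), 0.5)
    q = multipletests(p, method="fdr_bh")[1]
    fc = (x / T) / p0
    with np.errstate(divide="ignore"):
        log2_fc = np.log2(np.where(fc > 0, fc, np.nan))
    log2_fc = np.nan_to_num(log2_fc, nan=-np.inf)
    return pd.DataFrame(
        {
            "x": x,
            "p0": p0,
            "p": p,
            "q": q,
            "fold_change": fc,
            "log2_fc": log2_fc,
            "direction": np.where(fc >= 1.0, "up", "down"),
        },
        index=bio.gene_ids,
    )


def volcano_table(
    de: pd.DataFrame, fdr_threshold: float = 0.05, fold_change_min: float = 1.0
) -> pd.DataFrame:
    """Volcano-plot coordinates: log2 FC, -log10 q and a significance flag."""
    q = np.maximum(de["q"].to_numpy(dtype=float), np.finfo(float).eps)
    lfc = de["log2_fc"].to_numpy(dtype=float)
    flag = (de["q"].to_numpy() <= fdr_threshold) & (np.abs(lfc) >= np.log2(fold_change_min))
    return pd.DataFrame(
        {"log2_fc": lfc, "neg_log10_q": -np.log10(q), "significant": flag}, index=de.index
    )


def significant_genes(
    de: pd.DataFrame,
    fdr_threshold: float = 0.05,
    fold_change_min: float = 1.0,
    direction: str | None = None,
) -> list[str]:
    """Genes passing the FDR and linear fold-change thresholds."""
    v = volcano_table(de, fdr_threshold, fold_change_min)
    mask = v["significant"]
    if direction is not None:
        mask &= de["direction"] == direction
    return list(v.index[mask])
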