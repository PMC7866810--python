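"""Normalization and gene/cell filtering.

Three gene-filtering techniques are provided: expression filtering (minimum
normalized expression in a minimum number of cells), designed filtering
(restrict to a gene list of interest) and technical-noise filtering (keep
genes whose variability exceeds the noise level estimated from ERCC
spike-ins, following the Brennecke-style CV^2-vs-mean fit). Cell-level depth
filtering removes cells with too few raw reads.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .io import ExpressionTable

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationResult",
    "FilterParams",
    "NoiseFit",
    "compute_size_factors",
    "filter_by_expression",
    "median_expression_params",
    "filter_by_gene_list",
    "fit_technical_noise",
    "filter_by_noise",
]


@dataclass
class NormalizationResult:
    """Per-cell size factors and the depth-normalized matrix.

    ``normalized[g, c] = counts[g, c] / size_factors[c]``. Spike-in rows are
    excluded from size-factor estimation but are scaled by the same factors.
    """

    table: ExpressionTable
    size_factors: np.ndarray
    normalized: np.ndarray
    method: str

    def normalized_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.normalized, index=self.table.gene_ids, columns=self.table.cell_ids
        )


@dataclass
class FilterParams:
    """Expression-filter parameters.

    minexpr
        Minimum normalized expression a gene must reach.
    minnumber
        Minimum number of cells in which the gene must reach ``minexpr``.
    min_cell_counts
        Minimum raw total read count per cell; cells below are removed.
    gene_list
        Optional designed gene list applied after the expression rule.
    """

    minexpr: float = 5.0
    minnumber: int = 1
    min_cell_counts: float = 0.0
    gene_list: list[str] | None = None

    def __post_init__(self) -> None:
        if self.minexpr < 0:
            raise ValueError("minexpr must be >= 0")
        if int(self.minnumber) != self.minnumber or self.minnumber < 1:
            raise ValueError("minnumber must be an integer >= 1")
        if self.min_cell_counts < 0:
            raise ValueError("min_cell_counts must be >= 0")


@dataclass
class NoiseFit:
    """Fitted technical-noise law cv2(mu) = a1/mu + a0 and per-gene test results."""

    a0: float
    a1: float
    min_biol_disp: float
    alpha: float
    pvalues: pd.Series
    keep: pd.Series
    spikein_means: np.ndarray = field(default=None)  # type: ignore[assignment]
    spikein_cv2: np.ndarray = field(default=None)  # type: ignore[assignment]

    def curve(self, mu: np.ndarray) -> np.ndarray:
        return self.a1 / np.asarray(mu, dtype=float) + self.a0


def compute_size_factors(
    table: ExpressionTable, method: str = "scale_to_median_total"
) -> NormalizationResult:
    """Estimate per-cell size factors and normalize the count matrix.

    Two methods are offered:

    ``scale_to_median_total`` (default)
        ``factor[c] = total[c] / median(totals)``; every normalized column
        then sums to the median raw column total.
    ``median_of_ratios``
        DESeq-style geometric-mean-reference factors:
        ``factor[c] = median over reference genes of counts[g, c] / geomean_g``
        over genes with positive geometric mean across cells, rescaled so the
        factors have geometric mean 1.

    Spike-in rows do not contribute to factor estimation but are divided by
    the same factors.
    """
    bio = table.counts[~table.is_spikein, :]
    totals = bio.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        names = [table.cell_ids[i] for i in zero]
        raise ValueError(f"cells with zero total count: {names}")

    if method == "scale_to_median_total":
        factors = totals / np.median(totals)
    elif method == "median_of_ratios":
        logmat = np.log(bio, out=np.full_like(bio, -np.inf), where=bio > 0)
        loggeo = logmat.mean(axis=1)
        ref = np.isfinite(loggeo)
        if not ref.any():
            raise ValueError(
                "median_of_ratios: no gene is expressed in every cell; "
                "use scale_to_median_total or a pseudo-reference fallback"
            )
        ratios = np.exp(logmat[ref, :] - loggeo[ref, None])
        factors = np.median(ratios, axis=0)
        if (factors <= 0).any():
            raise ValueError("median_of_ratios produced a non-positive factor")
        factors = factors / np.exp(np.mean(np.log(factors)))
    else:
        raise ValueError(f"unknown normalization method {method!r}")

    normalized = table.counts / factors[None, :]
    return NormalizationResult(table, factors, normalized, method)


def median_expression_params(
    norm: NormalizationResult,
    cell_fraction: float = 0.10,
    min_cell_counts: float = 1000.0,
) -> FilterParams:
    """Convenience parameterization of the case-study filter.

    Sets ``minexpr`` to the overall median of the normalized biological
    values and ``minnumber`` to ``ceil(cell_fraction * n_cells)``, i.e. keep
    genes reaching the overall median expression in at least that fraction of
    the cells, and drop cells with fewer than ``min_cell_counts`` raw reads.
    """
    bio = norm.normalized[~norm.table.is_spikein, :]
    return FilterParams(
        minexpr=float(np.median(bio)),
        minnumber=int(math.ceil(cell_fraction * norm.table.n_cells)),
        min_cell_counts=min_cell_counts,
    )


def filter_by_expression(norm: NormalizationResult, params: FilterParams) -> ExpressionTable:
    """Apply the expression filter; returns the filtered biological table.

    Cells whose raw total (biological genes) is below ``min_cell_counts`` are
    removed first; then genes with normalized expression >= ``minexpr`` in at
    least ``minnumber`` of the surviving cells are kept. Spike-in rows are
    always removed from the output used downstream.
    """
    table = norm.table
    raw_totals = table.counts[~table.is_spikein, :].sum(axis=0)
    keep_cells = raw_totals >= params.min_cell_counts
    if not keep_cells.any():
        raise ValueError("every cell falls below min_cell_counts")

    normalized = norm.normalized[:, keep_cells]
    n_ok = (normalized >= params.minexpr).sum(axis=1)
    keep_genes = (n_ok >= params.minnumber) & ~table.is_spikein
    if not keep_genes.any():
        raise ValueError(
            "expression filter removed every gene; relax minexpr/minnumber"
        )
    out = table.subset_cells(keep_cells).subset_genes(keep_genes)
    if params.gene_list:
        out, _ = filter_by_gene_list(out, params.gene_list)
    return out


def filter_by_gene_list(
    table: ExpressionTable, gene_list: list[str]
) -> tuple[ExpressionTable, list[str]]:
    """Designed filtering: restrict to a gene list of interest.

    Matching is exact (case-sensitive); table order is preserved. Returns the
    filtered table and the list genes absent from the table.
    """
    if not gene_list:
        raise ValueError("gene list is empty")
    wanted = set(gene_list)
    keep = [i for i, g in enumerate(table.gene_ids) if g in wanted]
    missing = [g for g in dict.fromkeys(gene_list) if g not in set(table.gene_ids)]
    if not keep:
        raise ValueError("no gene from the list is present in the table")
    if missing:
        logger.info("%d of %d list genes absent from the table", len(missing), len(set(gene_list)))
    return table.subset_genes(keep), missing


def fit_technical_noise(
    norm: NormalizationResult,
    alpha: float = 0.01,
    min_biol_disp: float = 0.25,
    min_spikeins: int = 10,
    mean_quantile: float = 0.20,
) -> NoiseFit:
    """Fit the spike-in technical-noise law and test each biological gene.

    The squared coefficient of variation of the normalized spike-ins is
    modelled as ``cv2(mu) = a1/mu + a0`` and fitted by a Gamma-family GLM
    (identity link) on the regressor ``1/mu``, excluding spike-ins whose mean
    falls below the ``mean_quantile`` quantile. For every biological gene a
    chi-square test compares its observed total variance against the
    technical variance inflated by a minimum biological dispersion:

        statistic = var * (n - 1) / denom,
        denom = (a1 + min_biol_disp) * mu + (a0 + min_biol_disp) * mu^2

    with ``n - 1`` degrees of freedom; genes with upper-tail p <= alpha are
    flagged to keep.
    """
    table = norm.table
    spikes = norm.normalized[table.is_spikein, :]
    if spikes.shape[0] == 0:
        raise ValueError("no spike-in rows in the table")
    mu_s = spikes.mean(axis=1)
    pos = mu_s > 0
    if pos.sum() < min_spikeins:
        raise ValueError(
            f"need >= {min_spikeins} spike-ins with positive mean, have {int(pos.sum())}"
        )
    var_s = spikes.var(axis=1, ddof=1)
    mu_s, cv2_s = mu_s[pos], var_s[pos] / mu_s[pos] ** 2
    lo = np.quantile(mu_s, mean_quantile)
    use = mu_s >= lo
    a0, a1 = _fit_gamma_glm(mu_s[use], cv2_s[use])
    if (a1 / mu_s + a0 <= 0).any():
        raise ValueError(f"fitted noise curve non-positive on data range (a0={a0}, a1={a1})")

    bio = norm.normalized[~table.is_spikein, :]
    gene_ids = [g for g, s in zip(table.gene_ids, table.is_spikein) if not s]
    n = bio.shape[1]
    mu = bio.mean(axis=1)
    var = bio.var(axis=1, ddof=1)
    denom = (a1 + min_biol_disp) * mu + (a0 + min_biol_disp) * mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, var * (n - 1) / np.where(denom > 0, denom, 1.0), 0.0)
    pvals = scipy.stats.chi2.sf(stat, df=n - 1)
    pvals = np.where(denom > 0, pvals, 1.0)
    p = pd.Series(pvals, index=gene_ids, name="p")
    return NoiseFit(
        a0=float(a0),
        a1=float(a1),
        min_biol_disp=min_biol_disp,
        alpha=alpha,
        pvalues=p,
        keep=p <= alpha,
        spikein_means=mu_s,
        spikein_cv2=cv2_s,
    )


def _fit_gamma_glm(mu: np.ndarray, cv2: np.ndarray) -> tuple[float, float]:
    """Fit cv2 = a1 * (1/mu) + a0 by a Gamma GLM with identity link.

    Falls back to ordinary least squares if the GLM does not converge or
    yields a curve that is non-positive on the fitted range.
    """
    import warnings

    X = sm.add_constant(1.0 / mu)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(
                cv2, X, family=sm.families.Gamma(link=sm.families.links.Identity())
            ).fit()
        a0, a1 = float(fit.params[0]), float(fit.params[1])
        if np.all(a1 / mu + a0 > 0):
            return a0, a1
    except Exception:  # noqa: BLE001 - GLM may fail on degenerate inputs
        pass
    coef, _, _, _ = np.linalg.lstsq(X, cv2, rcond=None)
    return float(coef[0]), float(coef[1])


def filter_by_noise(norm: NormalizationResult, fit: NoiseFit) -> ExpressionTable:
    """Keep exactly the genes the noise fit flagged; spike-ins are excluded."""
    table = norm.table
    kept = set(fit.keep.index[fit.keep])
    if not kept:
        raise ValueError("noise filter flagged no gene; relax alpha or min_biol_disp")
    keep_idx = [
        i
        for i, (g, s) in enumerate(zip(table.gene_ids, table.is_spikein))
        if not s and g in kept
    ]
    return table.subset_genes(keep_idx)
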