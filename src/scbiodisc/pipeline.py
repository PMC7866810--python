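"""End-to-end pipeline orchestration from a single TOML config.

Stages run in order: preprocess -> cluster (+stability, outliers, embedding)
-> pseudotime -> differential expression -> biomarkers. Every stage writes
its result tables to the output directory and drops a ``<stage>.done``
marker; a rerun resumes after the last completed stage. A ``manifest.json``
records package version, seeds, parameters and input checksums so a run can
be reproduced exactly. All randomness flows from the single global seed via
per-stage derived seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import centrality, cross_validate, build_tree, enrich, induced_subnetwork
from .clustering import (
    ClusteringParams,
    OutlierParams,
    cluster_kmeans_gap,
    cluster_model_based,
    compute_embedding,
    detect_outliers,
    distance_matrix,
    jaccard_stability,
    log_transform,
    order_clusters_hierarchically,
    silhouette_widths,
)
from .diffexpr import DEParams, binomial_cluster_markers, samseq_two_class, significant_genes, volcano_table
from .io import read_counts, read_edge_list, read_gene_list, read_gmt, write_counts
from .preprocess import (
    FilterParams,
    compute_size_factors,
    filter_by_expression,
    filter_by_gene_list,
    filter_by_noise,
    fit_technical_noise,
    median_expression_params,
)
from .pseudotime import build_trajectory
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

STAGES = ("preprocess", "cluster", "pseudotime", "diffexpr", "biomarkers")


@dataclass
class PipelineConfig:
    counts: str
    outdir: str
    seed: int = 1
    spikein_prefix: str = "ERCC-"
    gene_list: str | None = None
    gmt: str | None = None
    edges: str | None = None
    preprocess: dict[str, Any] = field(default_factory=dict)
    cluster: dict[str, Any] = field(default_factory=dict)
    outliers: dict[str, Any] = field(default_factory=dict)
    diffexpr: dict[str, Any] = field(default_factory=dict)
    biomarkers: dict[str, Any] = field(default_factory=dict)
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("counts", "gene_list", "gmt", "edges"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name} = {p!r} does not exist")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    paths = raw.get("paths", {})
    cfg = PipelineConfig(
        counts=paths.get("counts", raw.get("counts", "")),
        outdir=paths.get("outdir", raw.get("outdir", "scbiodisc_out")),
        seed=raw.get("seed", 1),
        spikein_prefix=paths.get("spikein_prefix", raw.get("spikein_prefix", "ERCC-")),
        gene_list=paths.get("gene_list"),
        gmt=paths.get("gmt"),
        edges=paths.get("edges"),
        preprocess=raw.get("preprocess", {}),
        cluster=raw.get("cluster", {}),
        outliers=raw.get("outliers", {}),
        diffexpr=raw.get("diffexpr", {}),
        biomarkers=raw.get("biomarkers", {}),
        log_level=raw.get("log_level", "INFO"),
    )
    cfg.validate()
    return cfg


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig, resume: bool = True) -> Path:
    """Execute the four-stage pipeline; returns the output directory.

    Stage failure aborts with the failing stage named and a FAILED marker
    left beside any partial outputs.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in STAGES},
        "inputs": {
            name: {"path": str(p), "sha256": _checksum(p)}
            for name, p in (
                ("counts", config.counts),
                ("gene_list", config.gene_list),
                ("gmt", config.gmt),
                ("edges", config.edges),
            )
            if p
        },
        "params": {
            "preprocess": config.preprocess,
            "cluster": config.cluster,
            "outliers": config.outliers,
            "diffexpr": config.diffexpr,
            "biomarkers": config.biomarkers,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    stage = "preprocess"
    try:
        table = _run_preprocess(config, out, resume)
        stage = "cluster"
        result, dist, coords = _run_cluster(config, table, out, resume)
        stage = "pseudotime"
        _run_pseudotime(table, result, coords, out)
        stage = "diffexpr"
        de, markers = _run_diffexpr(config, table, result, out)
        stage = "biomarkers"
        _run_biomarkers(config, table, result, de, markers, out)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out


def _mark_done(out: Path, stage: str) -> None:
    (out / f"{stage}.done").write_text("")


def _run_preprocess(config: PipelineConfig, out: Path, resume: bool):
    if resume and (out / "preprocess.done").exists():
        logger.info("resuming: preprocess output reloaded")
        return read_counts(out / "filtered_counts.tsv", spikein_prefix=config.spikein_prefix)
    table = read_counts(config.counts, spikein_prefix=config.spikein_prefix)
    p = config.preprocess
    norm = compute_size_factors(table, p.get("norm", "scale_to_median_total"))
    if p.get("median10pct", False):
        params = median_expression_params(
            norm, min_cell_counts=p.get("min_cell_counts", 1000)
        )
    else:
        params = FilterParams(
            minexpr=p.get("minexpr", 5.0),
            minnumber=p.get("minnumber", 1),
            min_cell_counts=p.get("min_cell_counts", 0.0),
        )
    filtered = filter_by_expression(norm, params)
    if p.get("ercc_filter", False):
        fit = fit_technical_noise(
            norm, alpha=p.get("alpha", 0.01), min_biol_disp=p.get("min_biol_disp", 0.25)
        )
        noise_kept = set(filter_by_noise(norm, fit).gene_ids)
        keep = [i for i, g in enumerate(filtered.gene_ids) if g in noise_kept]
        filtered = filtered.subset_genes(keep)
        pd.DataFrame({"p": fit.pvalues, "keep": fit.keep}).to_csv(
            out / "noise_fit.tsv", sep="\t"
        )
    if config.gene_list:
        filtered, missing = filter_by_gene_list(filtered, read_gene_list(config.gene_list))
        (out / "missing_genes.txt").write_text("\n".join(missing) + "\n")
    write_counts(filtered, out / "filtered_counts.tsv")
    factors = pd.Series(norm.size_factors, index=table.cell_ids, name="size_factor")
    kept_cells = set(filtered.cell_ids)
    factors[[c in kept_cells for c in table.cell_ids]].to_csv(out / "size_factors.tsv", sep="\t")
    (out / "kept_genes.txt").write_text("\n".join(filtered.gene_ids) + "\n")
    _mark_done(out, "preprocess")
    return filtered


def _run_cluster(config: PipelineConfig, table, out: Path, resume: bool = False):
    c = config.cluster
    seed = _stage_seed(config.seed, "cluster")
    if resume and (out / "cluster.done").exists():
        logger.info("resuming: cluster labels reloaded")
        lab = pd.read_csv(out / "labels.tsv", sep="\t", index_col=0)["cluster"].to_numpy()
        X_log = log_transform(table.counts).T
        centers = np.vstack([X_log[lab == k].mean(axis=0) for k in np.unique(lab)])
        from .clustering import ClusteringResult

        result = ClusteringResult(
            labels=lab, k=int(np.unique(lab).size), centers=centers,
            distance=c.get("distance", "pearson"),
        )
        dist = distance_matrix(table, metric=c.get("heatmap_metric", "euclidean_of_correlation"))
        n_pcs = max(2, min(c.get("n_pcs", 20), table.n_cells - 1, table.n_genes))
        coords = PCA(n_components=n_pcs, random_state=seed).fit_transform(X_log)
        return result, dist, coords
    params = ClusteringParams(
        method=c.get("method", "kmeans"),
        k_range=(c.get("kmin", 1), c.get("kmax", 6)),
        distance=c.get("distance", "pearson"),
        n_bootstrap=c.get("bootstrap", 50),
        gap_refs=c.get("gap_refs", 50),
        seed=seed,
        n_pcs=c.get("n_pcs", 20),
        fixed_k=c.get("fixed_k"),
    )
    if params.method == "model_based":
        result = cluster_model_based(table, params)
        curve, curve_name = result.bic_curve, "bic.tsv"
    else:
        result = cluster_kmeans_gap(table, params)
        curve, curve_name = result.gap_curve, "gap.tsv"
    curve.to_csv(out / curve_name, sep="\t", index=False)
    pd.Series(result.labels, index=table.cell_ids, name="cluster").to_csv(
        out / "labels.tsv", sep="\t"
    )

    dist = distance_matrix(table, metric=c.get("heatmap_metric", "euclidean_of_correlation"))
    stability = jaccard_stability(table, result, params)
    rows = {"jaccard": stability.jaccard}
    if result.k >= 2:
        sil = silhouette_widths(dist, result.labels)
        rows["silhouette"] = sil.cluster_silhouette
        heat_order = order_clusters_hierarchically(dist, result.labels)
        (out / "heatmap_order.txt").write_text(",".join(map(str, heat_order)) + "\n")
    pd.DataFrame(rows).to_csv(out / "stability.tsv", sep="\t")

    o = config.outliers
    oparams = OutlierParams(
        probthr=o.get("probthr", 1e-3),
        outminc=o.get("outminc", 2),
    )
    report = detect_outliers(table, result, oparams)
    pd.DataFrame(
        {
            "outlier_genes": report.outlier_gene_counts,
            "min_p": report.min_p,
            "is_outlier": report.is_outlier,
        }
    ).to_csv(out / "outliers.tsv", sep="\t")

    emb = compute_embedding(table, method=c.get("embedding", "pca"), seed=seed)
    pd.DataFrame(emb.coordinates, index=table.cell_ids, columns=["dim1", "dim2"]).to_csv(
        out / "embedding.tsv", sep="\t"
    )

    X = log_transform(table.counts).T
    n_pcs = max(2, min(params.n_pcs, table.n_cells - 1, table.n_genes))
    coords = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    _mark_done(out, "cluster")
    return result, dist, coords


def _run_pseudotime(table, result, coords, out: Path) -> None:
    if result.k < 2:
        logger.warning("single cluster: pseudotime skipped")
        _mark_done(out, "pseudotime")
        return
    traj = build_trajectory(coords, result.labels)
    pd.DataFrame(
        {"pseudotime": traj.pseudotime, "order": np.argsort(traj.cell_order)},
        index=table.cell_ids,
    ).to_csv(out / "pseudotime.tsv", sep="\t")
    pd.DataFrame(traj.mst_edges, columns=["cluster_a", "cluster_b"]).to_csv(
        out / "mst_edges.tsv", sep="\t", index=False
    )
    _mark_done(out, "pseudotime")


def _run_diffexpr(config: PipelineConfig, table, result, out: Path):
    d = config.diffexpr
    seed = _stage_seed(config.seed, "diffexpr")
    params = DEParams(
        n_resamples=d.get("n_resamples", 20),
        n_permutations=d.get("n_permutations", 100),
        fdr_threshold=d.get("fdr", 0.05),
        fold_change_min=d.get("fc", 1.0),
        seed=seed,
    )
    sizes = result.cluster_sizes()
    ranked = sorted(sizes, key=lambda c: -sizes[c])
    a = d.get("cluster_a", ranked[0])
    b = d.get("cluster_b", ranked[1] if len(ranked) > 1 else ranked[0])
    mask = np.isin(result.labels, [a, b])
    sub = table.subset_cells(mask)
    groups = (result.labels[mask] == b).astype(int)
    de = samseq_two_class(sub, groups, params)
    de.to_csv(out / "de_table.tsv", sep="\t")
    volcano_table(de, params.fdr_threshold, params.fold_change_min).to_csv(
        out / "volcano.tsv", sep="\t"
    )
    markers = binomial_cluster_markers(table, result.labels, b, params)
    markers.to_csv(out / f"binomial_markers_cluster{b}.tsv", sep="\t")
    _mark_done(out, "diffexpr")
    return de, markers


def _run_biomarkers(config, table, result, de, markers, out: Path) -> None:
    bm = config.biomarkers
    d = config.diffexpr
    seed = _stage_seed(config.seed, "biomarkers")
    degs = significant_genes(de, d.get("fdr", 0.05), d.get("fc", 1.0))
    (out / "degs.txt").write_text("\n".join(degs) + "\n")

    sizes = result.cluster_sizes()
    ranked = sorted(sizes, key=lambda c: -sizes[c])
    a = d.get("cluster_a", ranked[0])
    b = d.get("cluster_b", ranked[1] if len(ranked) > 1 else ranked[0])
    mask = np.isin(result.labels, [a, b])
    feats = degs if degs else list(de.sort_values("q").index[:20])
    idx = [table.gene_index(g) for g in feats]
    expr = pd.DataFrame(
        log_transform(table.counts[idx][:, mask]).T,
        columns=feats,
        index=[c for c, m in zip(table.cell_ids, mask) if m],
    )
    labels = np.array([str(c) for c in result.labels[mask]])
    model = build_tree(expr, labels, inducer=bm.get("inducer", "cart"),
                       cp=bm.get("cp", 0.01), minsplit=bm.get("minsplit", 20), seed=seed)
    (out / "tree.json").write_text(model.to_json())
    (out / "tree.dot").write_text(model.to_dot())
    report = cross_validate(
        expr, labels, positive_class=str(b), inducer=bm.get("inducer", "cart"),
        n_folds=bm.get("folds", 10), cp=bm.get("cp", 0.01),
        minsplit=bm.get("minsplit", 20), seed=seed,
    )
    pd.DataFrame(
        [{
            "accuracy": report.accuracy,
            "sensitivity": report.sensitivity,
            "specificity": report.specificity,
            "tp": report.tp, "fn": report.fn, "tn": report.tn, "fp": report.fp,
        }]
    ).to_csv(out / "tree_cv.tsv", sep="\t", index=False)

    if config.edges and degs:
        net = read_edge_list(config.edges, min_weight=bm.get("min_weight", 0.4))
        sub, isolated = induced_subnetwork(net, degs)
        if len(sub):
            centrality(sub).to_csv(out / "hubs.tsv", sep="\t")
        (out / "isolated_genes.txt").write_text("\n".join(isolated) + "\n")
    if config.gmt and degs:
        sets = read_gmt(config.gmt)
        enrich(degs, sets, list(table.gene_ids)).to_csv(out / "enrichment.tsv", sep="\t")
    _mark_done(out, "biomarkers")
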