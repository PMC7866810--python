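"""Pseudo-temporal ordering of cells along a cluster-level trajectory.

A minimum spanning tree is built over the cluster centers in PCA space; the
tree's diameter (its longest path) is taken as the trajectory backbone, every
cell is projected orthogonally onto its nearest backbone segment, and
pseudotime is the cumulative arc length from the backbone start to the
projection point.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionTable

__all__ = ["TrajectoryResult", "build_trajectory", "expression_along_order"]


@dataclass
class TrajectoryResult:
    mst_edges: list[tuple[int, int]]  # 1-based cluster index pairs
    backbone: list[int]  # ordered cluster path along the tree diameter
    pseudotime: np.ndarray  # per cell, cumulative arc length
    cell_order: np.ndarray  # permutation sorting cells by pseudotime


def build_trajectory(coords: np.ndarray, labels: np.ndarray) -> TrajectoryResult:
    """Order cells along the MST backbone of the cluster centers.

    ``coords`` are the per-cell coordinates in the clustering PC space and
    ``labels`` the 1-based cluster assignment. The backbone is the weighted
    diameter of the Euclidean MST over cluster centers (ties broken by the
    lexicographically smallest endpoint pair); projection onto a segment is
    clamped to the segment, so cells beyond a terminal center receive the
    terminal arc length.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("pseudotime undefined for a single cluster")
    centers = {int(c): coords[labels == c].mean(axis=0) for c in clusters}

    G = nx.Graph()
    cl = [int(c) for c in clusters]
    for i, a in enumerate(cl):
        for b in cl[i + 1 :]:
            G.add_edge(a, b, weight=float(np.linalg.norm(centers[a] - centers[b])))
    mst = nx.minimum_spanning_tree(G, weight="weight")
    mst_edges = sorted(tuple(sorted(e)) for e in mst.edges)

    # diameter path: longest weighted path between leaves, lexicographic tie-break
    lengths = dict(nx.all_pairs_dijkstra_path_length(mst, weight="weight"))
    best = None
    for a in cl:
        for b in cl:
            if a >= b:
                continue
            key = (-lengths[a][b], a, b)
            if best is None or key < best[0]:
                best = (key, a, b)
    _, a, b = best
    backbone = nx.dijkstra_path(mst, a, b, weight="weight")

    pts = np.array([centers[c] for c in backbone])
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    seg_start = np.concatenate([[0.0], np.cumsum(seg_len)])[:-1]

    n = coords.shape[0]
    pt = np.empty(n)
    for i in range(n):
        best_d, best_t = np.inf, 0.0
        for s in range(len(backbone) - 1):
            p, q = pts[s], pts[s + 1]
            v = q - p
            L2 = v @ v
            t = 0.0 if L2 == 0 else float(np.clip((coords[i] - p) @ v / L2, 0.0, 1.0))
            proj = p + t * v
            d = float(np.linalg.norm(coords[i] - proj))
            if d < best_d:
                best_d = d
                best_t = seg_start[s] + t * seg_len[s]
        pt[i] = best_t
    order = np.lexsort((np.arange(n), pt))
    return TrajectoryResult(
        mst_edges=mst_edges, backbone=[int(c) for c in backbone], pseudotime=pt, cell_order=order
    )


def expression_along_order(
    table: ExpressionTable, cell_order: np.ndarray, genes: list[str]
) -> pd.DataFrame:
    """log10(x + 1) expression of the requested genes in pseudotime order.

    Rows are genes, columns are cells in trajectory order; intended for
    expression profiling along the ordering.
    """
    unknown = [g for g in genes if g not in set(table.gene_ids)]
    if unknown:
        raise KeyError(f"unknown genes: {unknown}")
    idx = [table.gene_index(g) for g in genes]
    ordered = np.asarray(cell_order)
    series = np.log10(table.counts[np.ix_(idx, ordered)] + 1.0)
    cols = [table.cell_ids[i] for i in ordered]
    return pd.DataFrame(series, index=genes, columns=cols)
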