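"""Biomarker identification: decision trees, network hubs and enrichment.

The decision-tree inducer is a CART-style recursive partitioner over gene
expression values: splits are exhaustive over (gene, midpoint threshold)
pairs minimizing weighted Gini impurity, with rpart-like stopping (node
purity, minimum split size, and a minimum relative impurity decrease cp
scaled by the root impurity). Performance is assessed by stratified k-fold
cross-validation. Network hubs are scored by connectivity degree and
(unnormalized) betweenness centrality on the DEG-induced subnetwork of an
offline protein-interaction edge list; gene-set enrichment is a one-sided
hypergeometric test with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .io import EdgeList, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "TreeNode",
    "DecisionTreeModel",
    "CVReport",
    "build_tree",
    "predict",
    "cross_validate",
    "induced_subnetwork",
    "centrality",
    "enrich",
    "gini",
]


# ---------------------------------------------------------------------------
# decision trees


@dataclass
class TreeNode:
    class_counts: dict[str, int]
    predicted_class: str
    gene: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None  # gene value < threshold
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.gene is None

    def to_dict(self) -> dict:
        d = {"class_counts": self.class_counts, "predicted_class": self.predicted_class}
        if not self.is_leaf:
            d.update(
                gene=self.gene,
                threshold=self.threshold,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d


@dataclass
class DecisionTreeModel:
    root: TreeNode
    inducer: str
    cp: float
    minsplit: int
    feature_names: list[str]
    classes: list[str] = field(default_factory=list)

    def decision_genes(self) -> list[str]:
        """Genes appearing at internal (decision) nodes, in traversal order."""
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                if node.gene not in out:
                    out.append(node.gene)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def n_decision_nodes(self) -> int:
        def count(node: TreeNode) -> int:
            return 0 if node.is_leaf else 1 + count(node.left) + count(node.right)

        return count(self.root)

    def to_json(self) -> str:
        return json.dumps(
            {"inducer": self.inducer, "cp": self.cp, "minsplit": self.minsplit,
             "tree": self.root.to_dict()},
            indent=2,
        )

    def to_dot(self) -> str:
        lines = ["digraph tree {", "  node [shape=box];"]
        counter = [0]

        def walk(node: TreeNode) -> int:
            nid = counter[0]
            counter[0] += 1
            if node.is_leaf:
                lines.append(f'  n{nid} [label="{node.predicted_class}\\n{node.class_counts}"];')
            else:
                lines.append(f'  n{nid} [label="{node.gene} < {node.threshold:g}"];')
                lid, rid = walk(node.left), walk(node.right)
                lines.append(f"  n{nid} -> n{lid} [label=yes];")
                lines.append(f"  n{nid} -> n{rid} [label=no];")
            return nid

        walk(self.root)
        lines.append("}")
        return "\n".join(lines)


@dataclass
class CVReport:
    n_folds: int
    fold_confusions: list[dict[str, int]]
    tp: int
    fn: int
    tn: int
    fp: int
    seed: int
    positive_class: str

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")


def gini(counts: np.ndarray) -> float:
    """Gini impurity of a class-count vector: 1 - sum p_i^2."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p**2).sum())


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def best_split(
    X: np.ndarray, y: np.ndarray, n_classes: int, inducer: str = "cart"
) -> tuple[int, float, float] | None:
    """Exhaustive search over (feature, midpoint threshold) splits.

    Returns (feature index, threshold, score) where the score is the weighted
    child Gini impurity (cart, lower is better, stored negated so larger is
    always better) or the gain ratio (c45). Constant features are never
    chosen. Ties break toward the lower feature index, then lower threshold.
    """
    n = y.size
    parent = np.bincount(y, minlength=n_classes)
    best: tuple[float, int, float] | None = None
    for j in range(X.shape[1]):
        vals = X[:, j]
        order = np.argsort(vals, kind="stable")
        sv, sy = vals[order], y[order]
        distinct = np.flatnonzero(np.diff(sv) > 0)
        if distinct.size == 0:
            continue  # constant feature
        left = np.zeros(n_classes, dtype=int)
        pos = 0
        for cut in distinct:
            while pos <= cut:
                left[sy[pos]] += 1
                pos += 1
            thr = (sv[cut] + sv[cut + 1]) / 2.0
            right = parent - left
            nl, nr = left.sum(), right.sum()
            if inducer == "cart":
                score = -(nl * gini(left) + nr * gini(right)) / n
            elif inducer == "c45":
                gain = _entropy(parent) - (nl * _entropy(left) + nr * _entropy(right)) / n
                if gain <= 1e-12:
                    continue
                split_info = _entropy(np.array([nl, nr]))
                score = gain / split_info if split_info > 0 else 0.0
            else:
                raise ValueError(f"unknown inducer {inducer!r}")
            if best is None or score > best[0] + 1e-12:
                best = (score, j, thr)
    if best is None:
        return None
    return best[1], best[2], best[0]


def build_tree(
    expr: pd.DataFrame,
    labels: np.ndarray,
    inducer: str = "cart",
    cp: float = 0.01,
    minsplit: int = 20,
    seed: int = 0,
) -> DecisionTreeModel:
    """Grow a classification tree over gene expression values.

    ``expr`` is samples x genes (typically restricted to a DEG list) and
    ``labels`` the class per sample. Growth stops when a node is pure, smaller
    than ``minsplit``, or when the best split's impurity decrease relative to
    the root impurity falls below ``cp``. The ``c45`` inducer replaces the
    Gini criterion with the entropy gain ratio (no error-based pruning;
    experimental).
    """
    y_raw = np.asarray(labels)
    classes = sorted({str(c) for c in y_raw})
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    cls_index = {c: i for i, c in enumerate(classes)}
    y = np.array([cls_index[str(c)] for c in y_raw])
    counts = np.bincount(y, minlength=len(classes))
    if (counts < 2).any():
        raise ValueError("need at least 2 samples per class")
    X = expr.to_numpy(dtype=float)
    names = [str(c) for c in expr.columns]
    n = y.size
    root_impurity = gini(np.bincount(y, minlength=len(classes)))

    def make_node(idx: np.ndarray) -> TreeNode:
        sub_counts = np.bincount(y[idx], minlength=len(classes))
        pred = classes[int(sub_counts.argmax())]
        node = TreeNode(
            class_counts={c: int(sub_counts[i]) for i, c in enumerate(classes)},
            predicted_class=pred,
        )
        node_gini = gini(sub_counts)
        if node_gini == 0.0 or idx.size < minsplit:
            return node
        found = best_split(X[idx], y[idx], len(classes), inducer)
        if found is None:
            return node
        j, thr, _ = found
        left_mask = X[idx, j] < thr
        nl, nr = int(left_mask.sum()), int((~left_mask).sum())
        child_gini = (
            nl * gini(np.bincount(y[idx][left_mask], minlength=len(classes)))
            + nr * gini(np.bincount(y[idx][~left_mask], minlength=len(classes)))
        ) / idx.size
        rel_decrease = idx.size * (node_gini - child_gini) / (n * max(root_impurity, 1e-12))
        if rel_decrease < cp:
            return node
        node.gene = names[j]
        node.threshold = float(thr)
        node.left = make_node(idx[left_mask])
        node.right = make_node(idx[~left_mask])
        return node

    root = make_node(np.arange(n))
    return DecisionTreeModel(
        root=root, inducer=inducer, cp=cp, minsplit=minsplit,
        feature_names=names, classes=classes,
    )


def predict(model: DecisionTreeModel, expr: pd.DataFrame) -> np.ndarray:
    """Predict the class of each sample (rows) from its expression values."""
    cols = {g: i for i, g in enumerate(expr.columns)}
    X = expr.to_numpy(dtype=float)

    def one(row: np.ndarray) -> str:
        node = model.root
        while not node.is_leaf:
            node = node.left if row[cols[node.gene]] < node.threshold else node.right
        return node.predicted_class

    return np.array([one(X[i]) for i in range(X.shape[0])])


def cross_validate(
    expr: pd.DataFrame,
    labels: np.ndarray,
    positive_class: str,
    inducer: str = "cart",
    n_folds: int = 10,
    cp: float = 0.01,
    minsplit: int = 20,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold cross-validation of the decision tree.

    Confusion counts are pooled over folds; sensitivity and specificity treat
    ``positive_class`` as positive. Fold sizes differ by at most one.
    """
    y = np.array([str(c) for c in np.asarray(labels)])
    n = y.size
    if n_folds > n:
        raise ValueError(f"n_folds {n_folds} exceeds n_samples {n}")
    min_class = min(np.bincount(pd.factorize(y)[0]))
    if n_folds > min_class:
        logger.warning("n_folds %d exceeds the smallest class size %d", n_folds, min_class)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    tp = fn = tn = fp = 0
    folds = []
    for train, test in skf.split(expr, y):
        model = build_tree(expr.iloc[train], y[train], inducer, cp, minsplit, seed)
        pred = predict(model, expr.iloc[test])
        truth = y[test]
        f_tp = int(((pred == positive_class) & (truth == positive_class)).sum())
        f_fn = int(((pred != positive_class) & (truth == positive_class)).sum())
        f_tn = int(((pred != positive_class) & (truth != positive_class)).sum())
        f_fp = int(((pred == positive_class) & (truth != positive_class)).sum())
        folds.append({"tp": f_tp, "fn": f_fn, "tn": f_tn, "fp": f_fp})
        tp, fn, tn, fp = tp + f_tp, fn + f_fn, tn + f_tn, fp + f_fp
    return CVReport(
        n_folds=n_folds, fold_confusions=folds, tp=tp, fn=fn, tn=tn, fp=fp,
        seed=seed, positive_class=positive_class,
    )


# ---------------------------------------------------------------------------
# network hubs


def induced_subnetwork(edges: EdgeList, genes: list[str]) -> tuple[EdgeList, list[str]]:
    """Subgraph induced on the query genes; isolated query genes reported separately."""
    if not genes:
        raise ValueError("gene list is empty")
    wanted = set(genes)
    sub = [(a, b, w) for a, b, w in edges.edges if a in wanted and b in wanted]
    connected = {n for e in sub for n in e[:2]}
    isolated = [g for g in dict.fromkeys(genes) if g not in connected]
    if not sub:
        logger.warning("no interaction among the %d query genes", len(wanted))
    return EdgeList(sub), isolated


def centrality(network: EdgeList) -> pd.DataFrame:
    """Degree and betweenness centrality with hub ranking.

    Betweenness is the unnormalized Brandes count over unweighted shortest
    paths, each unordered pair counted once. Hub rank sorts by descending
    degree, then descending betweenness, then gene id.
    """
    if len(network) == 0:
        raise ValueError("network is empty")
    G = nx.Graph()
    G.add_edges_from((a, b) for a, b, _ in network.edges)
    deg = dict(G.degree())
    btw = nx.betweenness_centrality(G, normalized=False)
    df = pd.DataFrame(
        {"degree": pd.Series(deg), "betweenness": pd.Series(btw)}
    ).sort_index()
    df = df.sort_values(
        by=["degree", "betweenness"], ascending=False, kind="stable"
    )
    df["hub_rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# enrichment


def enrich(
    query: list[str], sets: GeneSetCollection, universe: list[str]
) -> pd.DataFrame:
    """Hypergeometric gene-set over-representation of a query list.

    One-sided upper-tail p of drawing >= overlap set members in a query-sized
    sample from the universe; q-values by Benjamini-Hochberg across sets.
    Query genes outside the universe are dropped with a warning.
    """
    if not universe:
        raise ValueError("universe is empty")
    uni = set(universe)
    q = [g for g in dict.fromkeys(query) if g in uni]
    dropped = len(set(query)) - len(q)
    if dropped:
        logger.warning("%d query genes outside the universe were dropped", dropped)
    M, N = len(uni), len(q)
    rows = []
    for name, (_, members) in sets.sets.items():
        m = len(set(members) & uni)
        ov = len(set(members) & set(q))
        p = float(scipy.stats.hypergeom.sf(ov - 1, M, m, N)) if m else 1.0
        rows.append({"set": name, "overlap": ov, "set_size": m,
                     "universe_size": M, "query_size": N, "p": min(max(p, 0.0), 1.0)})
    df = pd.DataFrame(rows).set_index("set")
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df
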