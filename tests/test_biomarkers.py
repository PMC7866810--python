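import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.stats

from scbiodisc.biomarkers import (
    best_split,
    build_tree,
    centrality,
    cross_validate,
    CVReport,
    enrich,
    gini,
    induced_subnetwork,
    predict,
)
from scbiodisc.io import EdgeList, GeneSetCollection


class TestDecisionTree:
    def test_perfect_single_split(self):
        expr = pd.DataFrame({"GENE": [5.0] * 6 + [10.0] * 6})
        labels = np.array(["a"] * 6 + ["b"] * 6)
        model = build_tree(expr, labels, minsplit=2)
        assert model.n_decision_nodes() == 1
        assert model.root.gene == "GENE"
        assert model.root.threshold == 7.5
        assert (predict(model, expr) == labels).all()

    def test_gini_closed_form(self):
        assert gini(np.array([10, 0])) == 0.0
        assert gini(np.array([5, 5])) == pytest.approx(0.5)

    def test_split_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 10, size=(20, 3))
        y = rng.integers(0, 2, size=20)
        got = best_split(X, y, 2, "cart")
        assert got is not None
        j_got, thr_got, score_got = got

        best = None
        for j in range(3):
            vals = np.unique(X[:, j])
            for lo, hi in zip(vals[:-1], vals[1:]):
                thr = (lo + hi) / 2
                left, right = y[X[:, j] < thr], y[X[:, j] >= thr]
                w = (len(left) * gini(np.bincount(left, minlength=2))
                     + len(right) * gini(np.bincount(right, minlength=2))) / 20
                if best is None or w < best[0] - 1e-12:
                    best = (w, j, thr)
        assert j_got == best[1]
        assert thr_got == pytest.approx(best[2])
        assert -score_got == pytest.approx(best[0])

    def test_constant_feature_never_chosen(self):
        expr = pd.DataFrame({"FLAT": [1.0] * 8, "INFORMATIVE": [0.0] * 4 + [9.0] * 4})
        labels = np.array(["a"] * 4 + ["b"] * 4)
        model = build_tree(expr, labels, minsplit=2)
        assert "FLAT" not in model.decision_genes()

    def test_single_class_error(self):
        expr = pd.DataFrame({"G": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            build_tree(expr, np.array(["a", "a", "a"]))

    def test_training_accuracy_nonincreasing_in_cp(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.uniform(0, 10, size=(60, 4)),
                            columns=[f"G{i}" for i in range(4)])
        labels = np.where(expr["G0"] + rng.normal(0, 2, 60) > 5, "a", "b")
        prev = 1.1
        for cp in (0.0, 0.05, 0.2, 0.5):
            model = build_tree(expr, labels, cp=cp, minsplit=5)
            acc = (predict(model, expr) == labels).mean()
            assert acc <= prev + 1e-12
            prev = acc

    def test_c45_inducer_separates(self):
        expr = pd.DataFrame({"G": [1.0] * 5 + [8.0] * 5})
        labels = np.array(["a"] * 5 + ["b"] * 5)
        model = build_tree(expr, labels, inducer="c45", minsplit=2)
        assert (predict(model, expr) == labels).all()

    def test_json_and_dot_exports(self):
        expr = pd.DataFrame({"MARKER": [1.0] * 5 + [9.0] * 5})
        labels = np.array(["a"] * 5 + ["b"] * 5)
        model = build_tree(expr, labels, minsplit=2)
        assert "MARKER" in model.to_json()
        dot = model.to_dot()
        assert dot.startswith("digraph") and "MARKER" in dot


class TestCrossValidation:
    def test_confusion_formulas(self):
        rep = CVReport(n_folds=10, fold_confusions=[], tp=99, fn=1, tn=100, fp=0,
                       seed=0, positive_class="x")
        assert rep.accuracy == pytest.approx(0.995)
        assert rep.sensitivity == pytest.approx(0.99)
        assert rep.specificity == pytest.approx(1.0)

    def test_separable_simulation_high_accuracy(self):
        """A 10-fold-shifted marker separates two clusters almost perfectly,
        matching the quality of a tree built on strongly distinct
        sub-populations."""
        rng = np.random.default_rng(2)
        n = 200
        marker = np.concatenate([rng.lognormal(0, 0.3, n // 2),
                                 rng.lognormal(np.log(10), 0.3, n // 2)])
        noise = rng.uniform(0, 5, size=(n, 3))
        expr = pd.DataFrame(np.column_stack([marker, noise]),
                            columns=["MARKER", "N1", "N2", "N3"])
        labels = np.array(["c1"] * (n // 2) + ["c2"] * (n // 2))
        rep = cross_validate(expr, labels, positive_class="c2", seed=3)
        assert rep.accuracy >= 0.99
        assert rep.tp + rep.tn + rep.fp + rep.fn == n

    def test_same_seed_same_metrics(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.uniform(0, 10, size=(40, 3)), columns=list("ABC"))
        labels = np.array(["x"] * 20 + ["y"] * 20)
        a = cross_validate(expr, labels, "x", n_folds=5, seed=7)
        b = cross_validate(expr, labels, "x", n_folds=5, seed=7)
        assert (a.tp, a.fn, a.tn, a.fp) == (b.tp, b.fn, b.tn, b.fp)

    def test_too_many_folds_error(self):
        expr = pd.DataFrame({"G": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            cross_validate(expr, np.array(["a", "a", "b", "b"]), "a", n_folds=10)


class TestNetwork:
    def test_induced_subnetwork_example(self):
        net = EdgeList([("A", "B", 0.9), ("B", "C", 0.8), ("C", "D", 0.7)])
        sub, isolated = induced_subnetwork(net, ["A", "B", "C"])
        assert {(a, b) for a, b, _ in sub.edges} == {("A", "B"), ("B", "C")}
        assert isolated == []

    def test_disjoint_genes_empty_with_report(self):
        net = EdgeList([("A", "B", 0.9)])
        sub, isolated = induced_subnetwork(net, ["X", "Y"])
        assert len(sub) == 0
        assert isolated == ["X", "Y"]

    def test_path_and_star_betweenness(self):
        path = centrality(EdgeList([("A", "B", 1.0), ("B", "C", 1.0)]))
        assert path.loc["B", "betweenness"] == 1.0
        assert path.loc["A", "betweenness"] == 0.0
        star = centrality(EdgeList([("HUB", x, 1.0) for x in "XYZ"]))
        assert star.loc["HUB", "betweenness"] == 3.0  # C(3,2) pairs
        assert star["hub_rank"].tolist() == [1, 2, 3, 4]
        assert star.index[0] == "HUB"

    def test_random_graph_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        nodes = list("ABCDEFGH")
        edges = [(a, b, 1.0) for a, b in itertools.combinations(nodes, 2)
                 if rng.random() < 0.35]
        G = nx.Graph()
        G.add_edges_from((a, b) for a, b, _ in edges)
        got = centrality(EdgeList(edges))

        # exhaustive all-pairs shortest-path enumeration
        expect = {n: 0.0 for n in G.nodes}
        for s, t in itertools.combinations(G.nodes, 2):
            try:
                paths = list(nx.all_shortest_paths(G, s, t))
            except nx.NetworkXNoPath:
                continue
            for p in paths:
                for v in p[1:-1]:
                    expect[v] += 1.0 / len(paths)
        for n in G.nodes:
            assert got.loc[n, "betweenness"] == pytest.approx(expect[n], abs=1e-9)
            assert got.loc[n, "degree"] == G.degree[n]

    def test_tree_betweenness_sum_oracle(self):
        """On every tree with <= 6 nodes the betweenness total equals the sum
        over unordered pairs of (path length - 1): each interior vertex of the
        unique path counts once."""
        for n in range(3, 7):
            for tree in nx.nonisomorphic_trees(n):
                mapping = {v: f"N{v}" for v in tree.nodes}
                edges = [(mapping[a], mapping[b], 1.0) for a, b in tree.edges]
                tab = centrality(EdgeList(edges))
                expect = sum(
                    nx.shortest_path_length(tree, s, t) - 1
                    for s, t in itertools.combinations(tree.nodes, 2)
                )
                assert tab["betweenness"].sum() == pytest.approx(expect)

    def test_empty_network_error(self):
        with pytest.raises(ValueError):
            centrality(EdgeList([]))


class TestEnrichment:
    def _sets(self, members):
        return GeneSetCollection({"S": ("d", members)})

    def test_closed_form_full_overlap(self):
        universe = [f"U{i}" for i in range(20)]
        query = universe[:5]
        tab = enrich(query, self._sets(universe[:5]), universe)
        assert tab.loc["S", "p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    def test_zero_overlap_p_one(self):
        universe = [f"U{i}" for i in range(20)]
        tab = enrich(universe[:5], self._sets(universe[10:15]), universe)
        assert tab.loc["S", "p"] == pytest.approx(1.0)

    def test_matches_fisher_exact_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            M = int(rng.integers(15, 60))
            universe = [f"U{i}" for i in range(M)]
            set_size = int(rng.integers(2, M // 2))
            q_size = int(rng.integers(2, M // 2))
            members = list(rng.choice(universe, size=set_size, replace=False))
            query = list(rng.choice(universe, size=q_size, replace=False))
            tab = enrich(query, self._sets(members), universe)
            ov = tab.loc["S", "overlap"]
            table = [[ov, set_size - ov], [q_size - ov, M - set_size - q_size + ov]]
            _, fisher_p = scipy.stats.fisher_exact(table, alternative="greater")
            assert tab.loc["S", "p"] == pytest.approx(fisher_p, rel=1e-9)

    def test_relabeling_invariance(self):
        universe = [f"U{i}" for i in range(30)]
        members = universe[:8]
        query = universe[4:12]
        a = enrich(query, self._sets(members), universe)
        rename = {g: f"X{i}" for i, g in enumerate(universe)}
        b = enrich([rename[g] for g in query],
                   self._sets([rename[g] for g in members]),
                   [rename[g] for g in universe])
        assert a.loc["S", "p"] == pytest.approx(b.loc["S", "p"], rel=1e-12)

    def test_query_outside_universe_dropped(self):
        universe = [f"U{i}" for i in range(10)]
        tab = enrich(universe[:3] + ["ALIEN"], self._sets(universe[:3]), universe)
        assert tab.loc["S", "query_size"] == 3

    def test_empty_universe_error(self):
        with pytest.raises(ValueError):
            enrich(["A"], self._sets(["A"]), [])
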