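"""Jaccard kNN graph, Louvain clustering, annotation, abundance, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import igraph as ig
import imcpipe as ip
from imcpipe.phenotyping import (DEFAULT_PHENOTYPE_RULES,
                                 DEFAULT_SUBTYPE_RULES, restrict_rules)


class TestKnnGraph:
    def test_three_points_k2_jaccard_by_hand(self):
        X = np.array([[0.0], [1.0], [2.5]])
        g = ip.knn_graph(X, k=2)
        # every neighborhood is "the other two": |∩| = 1, |∪| = 3 for all pairs
        assert g.ecount() == 3
        assert np.allclose(g.es["weight"], 1 / 3)

    def test_n_not_greater_than_k_raises(self):
        with pytest.raises(ValueError, match="lower k"):
            ip.knn_graph(np.zeros((5, 2)), k=5)

    def test_duplicated_points_still_give_valid_graph(self):
        X = np.zeros((6, 2))
        X[3:] = 1.0
        g = ip.knn_graph(X, k=3)
        assert g.vcount() == 6
        assert all(0 < w <= 1 for w in g.es["weight"])

    def test_weights_in_unit_interval_and_graph_simple(self):
        rng = np.random.default_rng(0)
        g = ip.knn_graph(rng.normal(size=(80, 3)), k=10)
        assert all(0 < w <= 1 for w in g.es["weight"])
        assert g.is_simple()


class TestLouvain:
    def test_two_disconnected_cliques_found(self):
        g = ig.Graph.Full(10) + ig.Graph.Full(10)
        g.es["weight"] = 1.0
        labels = ip.louvain_cluster(g, seed=0)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_two_gaussian_blobs_ari_one(self):
        # marker-space-like dimensionality: low-dimensional geometric graphs
        # get locally oversplit by modularity optimization
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.3, (500, 10)),
                       rng.normal(5, 0.3, (500, 10))])
        truth = np.repeat([0, 1], 500)
        g = ip.knn_graph(X, k=100)
        labels = ip.louvain_cluster(g, seed=1)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        g = ip.knn_graph(rng.normal(size=(200, 4)), k=15)
        a = ip.louvain_cluster(g, seed=42)
        b = ip.louvain_cluster(g, seed=42)
        assert np.array_equal(a, b)

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError, match="empty"):
            ip.louvain_cluster(ig.Graph(), seed=0)

    def test_leiden_flag(self):
        g = ig.Graph.Full(10) + ig.Graph.Full(10)
        g.es["weight"] = 1.0
        labels = ip.louvain_cluster(g, seed=0, method="leiden")
        assert len(set(labels)) == 2


class TestUmap:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 5))
        a = ip.umap_embed(X, seed=9)
        b = ip.umap_embed(X, seed=9)
        assert a.shape == (60, 2)
        assert np.array_equal(a, b)

    def test_separated_types_stay_separated(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.2, (50, 4)), rng.normal(8, 0.2, (50, 4))])
        emb = ip.umap_embed(X, seed=1)
        intra = np.linalg.norm(emb[:50] - emb[:50].mean(0), axis=1).mean()
        inter = np.linalg.norm(emb[:50].mean(0) - emb[50:].mean(0))
        assert inter > intra

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            ip.umap_embed(np.zeros((5, 3)), seed=0)


class TestHeatmapAnnotation:
    def test_single_cluster_row_minmax(self):
        t = pd.DataFrame({"A_norm": [2.0, 2.0], "B_norm": [4.0, 4.0],
                          "C_norm": [6.0, 6.0]})
        heat = ip.cluster_heatmap(t, np.array([0, 0]))
        assert np.allclose(heat.loc[0], [0.0, 0.5, 1.0])

    def test_constant_row_maps_to_zeros(self):
        t = pd.DataFrame({"A_norm": [1.0], "B_norm": [1.0]})
        heat = ip.cluster_heatmap(t, np.array([0]))
        assert np.allclose(heat.loc[0], 0.0)

    def test_entries_in_unit_interval(self):
        rng = np.random.default_rng(6)
        t = pd.DataFrame(rng.random((50, 3)), columns=["A_norm", "B_norm", "C_norm"])
        heat = ip.cluster_heatmap(t, rng.integers(0, 4, 50))
        assert (heat.to_numpy() >= 0).all() and (heat.to_numpy() <= 1).all()

    def test_cd3_cd8_cluster_annotated_immune_cd8(self):
        markers = ["CD31", "Lyve-1", "CD45", "aSMA", "PDGFRb", "Desmin",
                   "Collagen I", "ZO-1", "CK19", "E-cadherin", "PanCK",
                   "F4/80", "Ly6G", "CD103", "B220", "CD3", "CD4", "CD8"]
        row = pd.DataFrame(0.0, index=[0], columns=markers)
        row.loc[0, ["CD3", "CD8", "CD45"]] = 1.0
        ann = ip.annotate_clusters(row)
        assert ann.loc[0, "phenotype"] == "immune"
        assert ann.loc[0, "immune_subtype"] == "CD8 T"

    def test_all_scores_below_min_score_fall_to_other(self):
        markers = [m for _, mk in DEFAULT_PHENOTYPE_RULES for m in mk] + \
                  [m for _, mk in DEFAULT_SUBTYPE_RULES for m in mk]
        row = pd.DataFrame(0.1, index=[0], columns=sorted(set(markers)))
        ann = ip.annotate_clusters(row)
        assert ann.loc[0, "phenotype"] == "other"

    def test_missing_rule_marker_raises(self):
        row = pd.DataFrame(1.0, index=[0], columns=["CD31"])
        with pytest.raises(KeyError, match="missing marker"):
            ip.annotate_clusters(row)

    def test_restrict_rules_drops_absent_markers(self):
        rules = restrict_rules(DEFAULT_PHENOTYPE_RULES,
                               ip.ORTHOTOPIC_CLUSTERING_MARKERS)
        tumor = dict(rules)["epithelial/tumor"]
        assert tumor == ["ZO-1"]
        with pytest.raises(KeyError, match="no markers left"):
            restrict_rules(DEFAULT_PHENOTYPE_RULES, ["CD3"])


def _abundance_table():
    rows = []
    rng = np.random.default_rng(7)
    for g, rois in (("core", ["c1", "c2", "c3"]), ("margin", ["m1", "m2", "m3"])):
        for roi in rois:
            phenos = (["epithelial/tumor"] * 100 + ["stromal"] * 50 +
                      ["immune"] * 50)
            subs = [None] * 150 + ["CD8 T"] * 30 + ["B"] * 20
            for p, s in zip(phenos, subs):
                rows.append({"roi_id": roi, "group": g, "phenotype": p,
                             "immune_subtype": s})
    return pd.DataFrame(rows)


class TestAbundance:
    def test_percent_arithmetic(self):
        t = _abundance_table()
        res = ip.abundance(t)
        per = res.per_roi
        row = per[(per.roi_id == "c1") & (per.label == "stromal")]
        assert row["percent"].iloc[0] == pytest.approx(25.0)

    def test_phenotype_percentages_sum_to_100_per_roi(self):
        res = ip.abundance(_abundance_table())
        per = res.per_roi
        sums = per[per.level == "phenotype"].groupby("roi_id")["percent"].sum()
        assert np.allclose(sums, 100.0, atol=1e-6)

    def test_subtype_percentages_relative_to_roi_cells(self):
        res = ip.abundance(_abundance_table())
        per = res.per_roi
        cd8 = per[(per.level == "immune_subtype") & (per.label == "CD8 T")]
        assert np.allclose(cd8["percent"], 15.0)

    def test_missing_group_raises(self):
        t = _abundance_table().drop(columns="group")
        with pytest.raises(ValueError, match="group"):
            ip.abundance(t)


class TestCompareAbundance:
    def test_sidak_closed_forms(self):
        assert ip.sidak_adjust(0.0, 6) == 0.0
        assert ip.sidak_adjust(0.01, 6) == pytest.approx(1 - 0.99 ** 6)
        assert ip.sidak_adjust(0.01, 6) == pytest.approx(0.0585, abs=5e-5)

    def test_planted_group_difference_detected(self):
        rng = np.random.default_rng(8)
        rows = []
        for g, shift in (("core", 0.0), ("margin", 30.0)):
            for i in range(5):
                a = 40 + shift + rng.normal(0, 2)
                rows += [
                    {"roi_id": f"{g}{i}", "group": g, "level": "phenotype",
                     "label": "epithelial/tumor", "percent": a},
                    {"roi_id": f"{g}{i}", "group": g, "level": "phenotype",
                     "label": "stromal", "percent": 100 - a},
                ]
        res = ip.compare_abundance(pd.DataFrame(rows))
        assert res["significant"].all()

    def test_single_roi_group_raises(self):
        rows = [{"roi_id": "a", "group": "g1", "level": "phenotype",
                 "label": "immune", "percent": 100.0},
                {"roi_id": "b", "group": "g2", "level": "phenotype",
                 "label": "immune", "percent": 100.0},
                {"roi_id": "c", "group": "g2", "level": "phenotype",
                 "label": "immune", "percent": 100.0}]
        with pytest.raises(ValueError, match=">= 2 ROIs"):
            ip.compare_abundance(pd.DataFrame(rows))

    def test_null_calibration_false_positive_rate(self):
        """Identical group distributions: adjusted rejections stay near alpha."""
        rng = np.random.default_rng(9)
        n_rep, n_clusters = 100, 4
        hits = total = 0
        for _ in range(n_rep):
            rows = []
            for g in ("g1", "g2"):
                for i in range(10):
                    p = rng.dirichlet(np.full(n_clusters, 5.0)) * 100
                    for c in range(n_clusters):
                        rows.append({"roi_id": f"{g}{i}", "group": g,
                                     "level": "phenotype", "label": f"c{c}",
                                     "percent": p[c]})
            res = ip.compare_abundance(pd.DataFrame(rows))
            hits += int(res["significant"].sum())
            total += n_clusters
        # Šídák guards the family; per-cluster false-positive rate stays
        # below alpha plus Monte Carlo slack
        assert hits / total <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)
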