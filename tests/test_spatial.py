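"""Boundary extraction, border-distance graph vs brute force, permutation test
vs exhaustive enumeration."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import imcpipe as ip


class TestBoundaryPixels:
    def test_3x3_square_has_8_boundary_pixels(self):
        mask = np.zeros((7, 7), dtype=int)
        mask[2:5, 2:5] = 1
        b = ip.boundary_pixels(mask)
        assert len(b[1]) == 8
        assert not any((r, c) == (3, 3) for r, c in b[1])

    def test_single_pixel_is_its_own_boundary(self):
        mask = np.zeros((5, 5), dtype=int)
        mask[2, 2] = 7
        b = ip.boundary_pixels(mask)
        assert np.array_equal(b[7], [[2, 2]])

    def test_boundary_sets_disjoint(self):
        mask = np.zeros((10, 10), dtype=int)
        mask[1:4, 1:4] = 1
        mask[1:4, 4:7] = 2  # touching cells
        b = ip.boundary_pixels(mask)
        s1 = {tuple(p) for p in b[1]}
        s2 = {tuple(p) for p in b[2]}
        assert not s1 & s2
        # touching edge pixels are boundary for both labels on their own side
        assert (1, 3) in s1 and (1, 4) in s2

    def test_image_edge_pixels_are_boundary(self):
        mask = np.ones((3, 3), dtype=int)
        b = ip.boundary_pixels(mask)
        assert len(b[1]) == 8  # all except the center


def _brute_force_edges(mask, radius):
    """All-pairs boundary-pixel minimum distance oracle."""
    b = ip.boundary_pixels(mask)
    labels = sorted(b)
    edges = set()
    for i, li in enumerate(labels):
        for lj in labels[i + 1:]:
            if cdist(b[li], b[lj]).min() < radius:
                edges.add((li, lj))
    return edges


class TestNeighborGraph:
    def test_two_point_cells_10um_apart_are_neighbors(self):
        mask = np.zeros((50, 50), dtype=int)
        mask[20, 10] = 1
        mask[20, 20] = 2
        g = ip.neighbor_graph(mask, radius=30.0)
        assert [(1, 2)] == [tuple(e) for e in g.edges]

    def test_cells_40um_apart_are_not_neighbors(self):
        mask = np.zeros((60, 60), dtype=int)
        mask[20, 5] = 1
        mask[20, 45] = 2
        g = ip.neighbor_graph(mask, radius=30.0)
        assert len(g.edges) == 0

    def test_border_distance_strictly_less_than_radius(self):
        mask = np.zeros((50, 50), dtype=int)
        mask[20, 5] = 1
        mask[20, 35] = 2  # exactly 30 µm: not neighbors
        g = ip.neighbor_graph(mask, radius=30.0)
        assert len(g.edges) == 0

    def test_empty_mask_gives_empty_graph(self):
        g = ip.neighbor_graph(np.zeros((20, 20), dtype=int))
        assert len(g.nodes) == 0 and len(g.edges) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_64px_fixtures(self, seed):
        spec = ip.LayoutSpec(mode="random", image_size=(64, 64),
                             n_cells={"A": 6, "B": 6},
                             min_center_distance=8.0, nucleus_radius=3.0,
                             ring_width=1.0)
        mask = ip.ground_truth_mask(ip.place_cells(spec, seed=seed), (64, 64),
                                    ring_width=1.0)
        g = ip.neighbor_graph(mask, radius=12.0)
        assert {tuple(e) for e in g.edges} == _brute_force_edges(mask, 12.0)

    def test_edges_invariant_under_geometry_preserving_relabel(self):
        spec = ip.LayoutSpec(mode="random", image_size=(64, 64),
                             n_cells={"A": 8}, min_center_distance=9.0)
        mask = ip.ground_truth_mask(ip.place_cells(spec, seed=3), (64, 64))
        perm = {0: 0, **{i: 9 - i for i in range(1, 9)}}
        relabeled = np.vectorize(perm.get)(mask)
        g1 = {tuple(e) for e in ip.neighbor_graph(mask, radius=15.0).edges}
        g2 = {tuple(e) for e in ip.neighbor_graph(relabeled, radius=15.0).edges}
        assert g2 == {tuple(sorted((perm[i], perm[j]))) for i, j in g1}


def _exhaustive_pvalues(edges, labels, pair):
    """Exact permutation p-values by enumerating every label permutation."""
    nodes = sorted({n for e in edges for n in e})
    adj = {n: [] for n in nodes}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)

    def stat(lab, a, b):
        cells_a = [n for n in nodes if lab[n] == a]
        if not cells_a:
            return np.nan
        return np.mean([sum(lab[m] == b for m in adj[n]) for n in cells_a])

    base = {n: l for n, l in zip(nodes, labels)}
    obs = stat(base, *pair)
    null = [stat({n: l for n, l in zip(nodes, perm)}, *pair)
            for perm in itertools.permutations(labels)]
    null = np.asarray(null)
    return obs, (null >= obs).mean(), (null <= obs).mean()


class TestInteractionTest:
    def _toy(self):
        # 6 nodes on a line, 1..6; edges between consecutive ones
        edges = np.array([(1, 2), (2, 3), (3, 4), (4, 5), (5, 6)])
        graph = ip.NeighborGraph(roi_id="t", nodes=np.arange(1, 7),
                                 edges=edges, radius=30.0)
        return graph

    def test_single_phenotype_scores_zero_with_p_one(self):
        graph = self._toy()
        res = ip.interaction_test_roi(graph, {n: "A" for n in range(1, 7)},
                                      n_perm=200, seed=0)
        assert res.p_enrich[0, 0] == 1.0
        assert res.p_deplete[0, 0] == 1.0
        assert res.score[0, 0] == 0.0

    @pytest.mark.parametrize("assignment", [
        ["A", "A", "A", "B", "B", "B"],
        ["A", "B", "A", "B", "A", "B"],
    ])
    def test_pvalues_match_exhaustive_enumeration(self, assignment):
        graph = self._toy()
        phenos = {n: a for n, a in zip(range(1, 7), assignment)}
        res = ip.interaction_test_roi(graph, phenos, n_perm=1000, seed=1,
                                      phenotype_order=["A", "B"])
        for (ai, a), (bi, b) in itertools.product(enumerate("AB"), repeat=2):
            obs, p_ge, p_le = _exhaustive_pvalues(
                [tuple(e) for e in graph.edges], assignment, (a, b))
            assert res.observed[ai, bi] == pytest.approx(obs)
            mc_tol = 3 * np.sqrt(p_ge * (1 - p_ge) / 1000) + 2 / 1000
            assert res.p_enrich[ai, bi] == pytest.approx(p_ge, abs=mc_tol + 0.002)
            mc_tol = 3 * np.sqrt(p_le * (1 - p_le) / 1000) + 2 / 1000
            assert res.p_deplete[ai, bi] == pytest.approx(p_le, abs=mc_tol + 0.002)

    def test_absent_phenotype_pairs_undefined(self):
        graph = self._toy()
        phenos = {n: "A" for n in range(1, 7)}
        res = ip.interaction_test_roi(graph, phenos, n_perm=200, seed=0,
                                      phenotype_order=["A", "B"])
        assert np.isnan(res.score[0, 1])
        assert np.isnan(res.score[1, 1])
        assert res.score[0, 0] == 0.0

    def test_seeded_determinism(self):
        graph = self._toy()
        phenos = {n: p for n, p in zip(range(1, 7), "AABABB")}
        r1 = ip.interaction_test_roi(graph, phenos, n_perm=500, seed=5)
        r2 = ip.interaction_test_roi(graph, phenos, n_perm=500, seed=5)
        assert np.array_equal(r1.p_enrich, r2.p_enrich, equal_nan=True)
        assert np.array_equal(r1.score, r2.score, equal_nan=True)

    def test_node_without_phenotype_raises(self):
        graph = self._toy()
        with pytest.raises(ValueError, match="without phenotype"):
            ip.interaction_test_roi(graph, {1: "A"}, n_perm=200, seed=0)


class TestAggregateScores:
    def _result(self, score):
        p = np.full_like(score, 0.5, dtype=float)
        return ip.InteractionResult(
            roi_id="r", phenotypes=["A", "B"], observed=p, p_enrich=p,
            p_deplete=p, score=np.asarray(score, dtype=float),
            n_permutations=1000, alpha=0.01, seed=0)

    def test_mean_of_scores(self):
        rs = [self._result([[1, 1], [0, 0]]),
              self._result([[1, 0], [0, 0]]),
              self._result([[0, 0], [0, -1]])]
        agg = ip.aggregate_scores(rs)
        assert agg.loc["A", "A"] == pytest.approx(2 / 3)
        assert agg.loc["B", "B"] == pytest.approx(-1 / 3)

    def test_single_roi_identity(self):
        r = self._result([[1, -1], [0, 1]])
        agg = ip.aggregate_scores([r])
        assert np.array_equal(agg.to_numpy(), r.score)

    def test_undefined_pairs_excluded_from_mean(self):
        a = self._result([[1, np.nan], [0, 0]])
        b = self._result([[0, 1], [0, 0]])
        agg = ip.aggregate_scores([a, b])
        assert agg.loc["A", "A"] == pytest.approx(0.5)
        assert agg.loc["A", "B"] == pytest.approx(1.0)  # only ROI b defined

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            ip.aggregate_scores([])
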