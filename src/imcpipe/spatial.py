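"""Border-distance neighbor graph and permutation interaction scores.

Two cells are neighbors when the minimum Euclidean distance between their
boundary pixels is below 30 µm. Per ROI and ordered phenotype pair (A, B),
the observed statistic is the mean number of B neighbors per A cell; its null
is built by permuting the phenotype labels over the fixed graph (n = 1000).
Significant enrichment scores +1, depletion −1 (p < 0.01, add-one permutation
p-values, ties counted toward the null), otherwise 0; ROI scores are averaged
into a directed phenotype-pair matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

DEFAULT_RADIUS_UM = 30.0
DEFAULT_N_PERM = 1000
DEFAULT_ALPHA = 0.01


def boundary_pixels(mask: np.ndarray) -> dict[int, np.ndarray]:
    """Per-label boundary coordinates: pixels 4-adjacent to another value.

    Returns label -> (N, 2) array of (row, col). Boundary sets are disjoint
    since each pixel has exactly one label.
    """
    mask = np.asarray(mask)
    boundary = np.zeros(mask.shape, dtype=bool)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        neigh = np.roll(mask, shift, axis=axis)
        diff = mask != neigh
        # roll wraps around; edge pixels are boundary by definition
        if axis == 0:
            edge = (slice(0, 1), slice(None)) if shift == 1 else (slice(-1, None), slice(None))
        else:
            edge = (slice(None), slice(0, 1)) if shift == 1 else (slice(None), slice(-1, None))
        diff[edge] = True
        boundary |= diff
    boundary &= mask > 0
    rr, cc = np.nonzero(boundary)
    labels = mask[rr, cc]
    order = np.argsort(labels, kind="stable")
    rr, cc, labels = rr[order], cc[order], labels[order]
    out: dict[int, np.ndarray] = {}
    for lab, start, stop in zip(*_runs(labels)):
        out[int(lab)] = np.column_stack([rr[start:stop], cc[start:stop]])
    return out


def _runs(sorted_labels: np.ndarray):
    uniq, starts = np.unique(sorted_labels, return_index=True)
    stops = np.append(starts[1:], len(sorted_labels))
    return uniq, starts, stops


@dataclass
class NeighborGraph:
    """Undirected cell adjacency for one ROI under the border-distance rule."""

    roi_id: str
    nodes: np.ndarray   # cell labels present in the mask
    edges: np.ndarray   # (E, 2) label pairs, i < j, unique
    radius: float       # µm

    def degree(self) -> dict[int, int]:
        deg = dict.fromkeys(self.nodes.tolist(), 0)
        for i, j in self.edges:
            deg[int(i)] += 1
            deg[int(j)] += 1
        return deg


def neighbor_graph(mask: np.ndarray, radius: float = DEFAULT_RADIUS_UM,
                   pixel_size: float = 1.0, roi_id: str = "roi") -> NeighborGraph:
    """Cells whose border-to-border distance is strictly below ``radius`` µm.

    Exact: a k-d tree over all boundary pixels finds every boundary-pixel pair
    within the radius, which is equivalent to the brute-force all-pairs
    minimum.
    """
    bounds = boundary_pixels(mask)
    nodes = np.asarray(sorted(bounds), dtype=np.int64)
    if len(nodes) == 0:
        return NeighborGraph(roi_id=roi_id, nodes=nodes,
                             edges=np.empty((0, 2), dtype=np.int64), radius=radius)
    pts = np.concatenate([bounds[n] for n in nodes]).astype(float)
    labs = np.concatenate([np.full(len(bounds[n]), n) for n in nodes])
    r_px = radius / pixel_size
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r_px, output_type="ndarray")
    if len(pairs) == 0:
        return NeighborGraph(roi_id=roi_id, nodes=nodes,
                             edges=np.empty((0, 2), dtype=np.int64), radius=radius)
    d2 = ((pts[pairs[:, 0]] - pts[pairs[:, 1]]) ** 2).sum(axis=1)
    pairs = pairs[d2 < r_px ** 2]  # strict inequality
    li, lj = labs[pairs[:, 0]], labs[pairs[:, 1]]
    keep = li != lj
    lo = np.minimum(li[keep], lj[keep])
    hi = np.maximum(li[keep], lj[keep])
    edges = np.unique(np.column_stack([lo, hi]), axis=0).astype(np.int64)
    return NeighborGraph(roi_id=roi_id, nodes=nodes, edges=edges, radius=radius)


@dataclass
class InteractionResult:
    """Directed phenotype-pair interaction test for one ROI.

    Matrices are (P, P) over ``phenotypes`` with rows = phenotype A of the
    center cell and columns = phenotype B of the neighbors. Pairs whose A or B
    phenotype is absent from the ROI are NaN (undefined).
    """

    roi_id: str
    phenotypes: list[str]
    observed: np.ndarray
    p_enrich: np.ndarray
    p_deplete: np.ndarray
    score: np.ndarray
    n_permutations: int
    alpha: float
    seed: int

    def score_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.score, index=self.phenotypes,
                            columns=self.phenotypes)


def interaction_test_roi(graph: NeighborGraph, phenotypes: dict[int, str],
                         n_perm: int = DEFAULT_N_PERM,
                         alpha: float = DEFAULT_ALPHA, seed: int = 0,
                         phenotype_order: list[str] | None = None,
                         ) -> InteractionResult:
    """Label-permutation test of phenotype co-localization on a fixed graph.

    For each ordered pair (A, B): observed = mean number of B-phenotype
    neighbors per A-phenotype cell; the null re-computes it under ``n_perm``
    uniform permutations of the labels over the nodes. p_enrich =
    (1 + #{null >= obs}) / (n_perm + 1) and symmetrically for depletion;
    score is +1 / −1 when the corresponding p-value is below ``alpha``, else 0.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    nodes = graph.nodes
    missing = [int(n) for n in nodes if n not in phenotypes]
    if missing:
        raise ValueError(f"nodes without phenotype: {missing[:5]}...")
    labels = np.asarray([phenotypes[int(n)] for n in nodes])
    order = phenotype_order or sorted(set(labels))
    extra = set(labels) - set(order)
    if extra:
        raise ValueError(f"phenotypes missing from phenotype_order: {extra}")
    p_count = len(order)
    code = {ph: i for i, ph in enumerate(order)}
    lab = np.asarray([code[x] for x in labels])
    counts = np.bincount(lab, minlength=p_count).astype(float)

    node_idx = {int(n): i for i, n in enumerate(nodes)}
    if len(graph.edges):
        eu = np.asarray([node_idx[int(i)] for i in graph.edges[:, 0]])
        ev = np.asarray([node_idx[int(j)] for j in graph.edges[:, 1]])
        du = np.concatenate([eu, ev])  # both directions
        dv = np.concatenate([ev, eu])
    else:
        du = dv = np.empty(0, dtype=np.int64)

    def _pair_sums(codes: np.ndarray) -> np.ndarray:
        return np.bincount(codes[du] * p_count + codes[dv],
                           minlength=p_count * p_count
                           ).reshape(p_count, p_count).astype(float)

    safe = np.where(counts > 0, counts, 1.0)
    observed = _pair_sums(lab) / safe[:, None]

    rng = np.random.default_rng(seed)
    ge = np.zeros((p_count, p_count), dtype=np.int64)
    le = np.zeros((p_count, p_count), dtype=np.int64)
    for _ in range(n_perm):
        null = _pair_sums(lab[rng.permutation(len(lab))]) / safe[:, None]
        ge += null >= observed
        le += null <= observed
    p_enrich = (1.0 + ge) / (n_perm + 1.0)
    p_deplete = (1.0 + le) / (n_perm + 1.0)

    score = np.zeros((p_count, p_count))
    score[p_enrich < alpha] = 1.0
    score[p_deplete < alpha] = -1.0
    undefined = (counts == 0)[:, None] | (counts == 0)[None, :]
    for arr in (observed, p_enrich, p_deplete, score):
        arr[undefined] = np.nan
    return InteractionResult(roi_id=graph.roi_id, phenotypes=list(order),
                             observed=observed, p_enrich=p_enrich,
                             p_deplete=p_deplete, score=score,
                             n_permutations=n_perm, alpha=alpha, seed=seed)


def aggregate_scores(results: list[InteractionResult]) -> pd.DataFrame:
    """ROI-averaged directed score matrix in [−1, 1].

    Undefined (phenotype-absent) pairs are excluded from each pair's mean; a
    pair undefined in every ROI stays NaN. All results must share the
    phenotype order.
    """
    if not results:
        raise ValueError("no interaction results to aggregate")
    order = results[0].phenotypes
    for r in results[1:]:
        if r.phenotypes != order:
            raise ValueError("results have inconsistent phenotype order")
    stack = np.stack([r.score for r in results])
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        mean = np.nanmean(stack, axis=0)
    return pd.DataFrame(mean, index=order, columns=order)
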