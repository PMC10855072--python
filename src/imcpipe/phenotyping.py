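"""Phenograph-style clustering, UMAP embedding, cluster annotation and
abundance comparison.

Clustering follows the classic cytometry recipe: a k-nearest-neighbor graph
(k = 100) with Jaccard edge weights over the k-neighborhoods, partitioned by
Louvain modularity optimization. Clusters are annotated into six phenotype
classes (epithelial/tumor, stromal, immune, endothelial, lymphatic, other) by
lineage-marker scores on the row-normalized cluster-mean matrix, and immune
clusters are sub-typed (mono/macrophage, dendritic, neutrophil, CD4 T, CD8 T,
B). Per-ROI abundances are compared between groups with a two-way ANOVA and
Šídák-adjusted per-cluster contrasts.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.neighbors import NearestNeighbors

PHENOTYPE_CLASSES = ("epithelial/tumor", "stromal", "immune", "endothelial",
                     "lymphatic", "other")

#: ordered (class, markers) lineage rules; scored on row-normalized means
DEFAULT_PHENOTYPE_RULES: list[tuple[str, list[str]]] = [
    ("endothelial", ["CD31"]),
    ("lymphatic", ["Lyve-1"]),
    ("immune", ["CD45"]),
    ("stromal", ["aSMA", "PDGFRb", "Desmin", "Collagen I"]),
    ("epithelial/tumor", ["ZO-1", "CK19", "E-cadherin", "PanCK"]),
]

DEFAULT_SUBTYPE_RULES: list[tuple[str, list[str]]] = [
    ("mono/macrophage", ["F4/80"]),
    ("neutrophil", ["Ly6G"]),
    ("dendritic", ["CD103"]),
    ("B", ["B220"]),
    ("CD4 T", ["CD3", "CD4"]),
    ("CD8 T", ["CD3", "CD8"]),
]


# --------------------------------------------------------------------------- #
# graph construction and clustering


def knn_graph(X: np.ndarray, k: int = 100) -> ig.Graph:
    """Jaccard-weighted kNN graph over cells.

    Directed k-nearest neighborhoods (Euclidean, self excluded, ties broken by
    index order) are converted to an undirected graph whose edge weights are
    the Jaccard overlap |N(i) ∩ N(j)| / |N(i) ∪ N(j)| of the two
    k-neighborhoods; zero-weight edges are dropped.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n <= k:
        raise ValueError(f"n = {n} cells <= k = {k}; lower k")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    # drop self from each neighborhood (may not be first among duplicates)
    rows = np.arange(n)
    neigh = np.empty((n, k), dtype=np.int64)
    for i in rows:
        cand = idx[i][idx[i] != i][:k]
        if len(cand) < k:  # self not returned at all (duplicate points)
            cand = idx[i][:k]
        neigh[i] = cand

    adj = sparse.csr_matrix(
        (np.ones(n * k, dtype=np.int32),
         (np.repeat(rows, k), neigh.ravel())), shape=(n, n))
    inter = adj @ adj.T  # |N(i) ∩ N(j)| for all overlapping pairs
    cand = adj.maximum(adj.T).tocoo()  # candidate edges: j ∈ N(i) or i ∈ N(j)
    ei, ej = cand.row, cand.col
    keep = ei < ej
    ei, ej = ei[keep], ej[keep]
    inter_e = np.asarray(inter[ei, ej]).ravel()
    union_e = 2 * k - inter_e
    w = inter_e / union_e
    nz = w > 0
    g = ig.Graph(n=n, edges=list(zip(ei[nz].tolist(), ej[nz].tolist())),
                 edge_attrs={"weight": w[nz].tolist()})
    return g


def louvain_cluster(graph: ig.Graph, seed: int, method: str = "louvain") -> np.ndarray:
    """Community labels by modularity optimization; deterministic given seed.

    ``method`` is ``louvain`` (igraph multilevel, the phenograph default here)
    or ``leiden``. Singleton components keep their own label.
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    weights = graph.es["weight"] if "weight" in graph.edge_attributes() else None
    if method == "louvain":
        state = random.getstate()
        try:
            random.seed(seed)
            part = graph.community_multilevel(weights=weights)
        finally:
            random.setstate(state)
        return np.asarray(part.membership)
    if method == "leiden":
        import leidenalg

        part = leidenalg.find_partition(
            graph, leidenalg.ModularityVertexPartition, weights=weights, seed=seed)
        return np.asarray(part.membership)
    raise ValueError(f"unknown method {method!r}")


def umap_embed(X: np.ndarray, seed: int, n_neighbors: int = 15) -> np.ndarray:
    """2-D UMAP embedding for visualization (clustering never depends on it)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 points to embed")
    if X.shape[0] <= n_neighbors:
        raise ValueError("fewer points than the n_neighbors parameter")
    import umap

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*n_jobs.*")
        warnings.filterwarnings("ignore", message=".*TBB.*")
        emb = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        random_state=seed).fit_transform(X)
    return np.asarray(emb)


# --------------------------------------------------------------------------- #
# annotation


def cluster_heatmap(table: pd.DataFrame, labels: np.ndarray,
                    markers: list[str] | None = None,
                    row_norm: str = "minmax") -> pd.DataFrame:
    """Cluster × marker matrix: per-cluster mean, normalized per row.

    Rows are min-max scaled to [0, 1] (``row_norm='zscore'`` standardizes
    instead); a constant row maps to all zeros.
    """
    if markers is None:
        markers = [c for c in table.columns if c.endswith("_norm")]
    if len(table) != len(labels):
        raise ValueError("labels must align with the table rows")
    means = table[markers].groupby(np.asarray(labels)).mean()
    if row_norm == "minmax":
        lo = means.min(axis=1)
        rng = means.max(axis=1) - lo
        out = means.sub(lo, axis=0).div(rng.where(rng > 0, np.inf), axis=0)
    elif row_norm == "zscore":
        sd = means.std(axis=1)
        out = means.sub(means.mean(axis=1), axis=0).div(
            sd.where(sd > 0, np.inf), axis=0)
    else:
        raise ValueError(f"unknown row_norm {row_norm!r}")
    out.index.name = "cluster_id"
    return out


def restrict_rules(rules: list[tuple[str, list[str]]],
                   markers: list[str]) -> list[tuple[str, list[str]]]:
    """Drop rule markers that are not in ``markers`` (e.g. the orthotopic
    clustering panel omits CK19/E-cadherin/PanCK, leaving ZO-1 to identify the
    tumor class). A rule losing all its markers is an error."""
    out = []
    for cls, mk in rules:
        kept = [m for m in mk if m in markers]
        if not kept:
            raise KeyError(f"rule {cls!r} has no markers left from {mk}")
        out.append((cls, kept))
    return out


def _score(row: pd.Series, markers: list[str]) -> float:
    missing = [m for m in markers if m not in row.index]
    if missing:
        raise KeyError(f"annotation rule references missing marker(s): {missing}")
    return float(row[markers].mean())


def annotate_clusters(cluster_means: pd.DataFrame,
                      rules: list[tuple[str, list[str]]] | None = None,
                      subtype_rules: list[tuple[str, list[str]]] | None = None,
                      min_score: float = 0.5) -> pd.DataFrame:
    """Assign a phenotype class (and immune subtype) to each cluster.

    ``cluster_means`` is the row-normalized cluster × marker matrix (as from
    :func:`cluster_heatmap`, with marker column names optionally carrying a
    ``_norm`` suffix). Per class, score = mean of the class markers' values;
    the arg-max class is assigned if its score >= ``min_score``, otherwise
    "other". Ties go to the earlier rule. Immune clusters are sub-typed the
    same way over the subtype rules.
    """
    rules = DEFAULT_PHENOTYPE_RULES if rules is None else rules
    subtype_rules = DEFAULT_SUBTYPE_RULES if subtype_rules is None else subtype_rules
    means = cluster_means.rename(
        columns=lambda c: c[:-5] if c.endswith("_norm") else c)
    out = []
    for cid, row in means.iterrows():
        scores = [(cls, _score(row, mk)) for cls, mk in rules]
        best_cls, best = max(scores, key=lambda t: t[1])
        # earlier rule wins ties
        for cls, s in scores:
            if s == best:
                best_cls = cls
                break
        phenotype = best_cls if best >= min_score else "other"
        subtype = None
        if phenotype == "immune":
            sub_scores = [(cls, _score(row, mk)) for cls, mk in subtype_rules]
            sub_cls, sub_best = max(sub_scores, key=lambda t: t[1])
            for cls, s in sub_scores:
                if s == sub_best:
                    sub_cls = cls
                    break
            subtype = sub_cls if sub_best >= min_score else "other"
        out.append({"cluster_id": cid, "phenotype": phenotype,
                    "immune_subtype": subtype})
    return pd.DataFrame(out).set_index("cluster_id")


@dataclass
class PhenotypingResult:
    labels: np.ndarray
    heatmap: pd.DataFrame
    annotation: pd.DataFrame
    umap_xy: np.ndarray | None = None


def phenotype_cells(table: pd.DataFrame, markers: list[str], seed: int,
                    k: int = 100, min_score: float = 0.5,
                    rules=None, subtype_rules=None,
                    small_cluster_fraction: float = 0.005,
                    embed: bool = False, method: str = "louvain",
                    restrict_to_markers: bool = True,
                    ) -> tuple[pd.DataFrame, PhenotypingResult]:
    """Full phenotyping pass: kNN graph → Louvain → annotate → per-cell labels.

    ``markers`` are the clustering markers; their ``<marker>_norm`` columns
    must exist. Clusters below ``small_cluster_fraction`` of cells fall to
    "other". Returns the table with ``cluster_id``/``phenotype``/
    ``immune_subtype`` columns plus the intermediate results.
    """
    cols = [m + "_norm" for m in markers]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"missing normalized columns: {missing}")
    if restrict_to_markers:
        rules = restrict_rules(
            DEFAULT_PHENOTYPE_RULES if rules is None else rules, markers)
        subtype_rules = restrict_rules(
            DEFAULT_SUBTYPE_RULES if subtype_rules is None else subtype_rules,
            markers)
    X = table[cols].to_numpy()
    g = knn_graph(X, k=k)
    labels = louvain_cluster(g, seed=seed, method=method)
    heat = cluster_heatmap(table, labels, markers=cols)
    ann = annotate_clusters(heat, rules=rules, subtype_rules=subtype_rules,
                            min_score=min_score)
    counts = pd.Series(labels).value_counts()
    small = counts[counts < small_cluster_fraction * len(labels)].index
    ann.loc[ann.index.isin(small), "phenotype"] = "other"
    ann.loc[ann.index.isin(small), "immune_subtype"] = None

    out = table.copy()
    out["cluster_id"] = labels
    out["phenotype"] = ann["phenotype"].reindex(labels).to_numpy()
    out["immune_subtype"] = ann["immune_subtype"].reindex(labels).to_numpy()
    xy = umap_embed(X, seed=seed) if embed else None
    return out, PhenotypingResult(labels=labels, heatmap=heat, annotation=ann,
                                  umap_xy=xy)


# --------------------------------------------------------------------------- #
# abundance and group comparison


@dataclass
class AbundanceResult:
    per_roi: pd.DataFrame     # roi_id, group, level, label, percent
    group_means: pd.DataFrame  # group, level, label, mean_percent


def abundance(table: pd.DataFrame, group_assignment: dict[str, str] | None = None,
              ) -> AbundanceResult:
    """Percent of each ROI's cells per phenotype and per immune subtype.

    ``group_assignment`` maps roi_id to group (e.g. core/margin); if omitted a
    ``group`` column must be present. Per-ROI phenotype percentages sum to 100.
    Empty ROIs are excluded with a warning.
    """
    t = table.copy()
    if group_assignment is not None:
        t["group"] = t["roi_id"].map(group_assignment)
    if "group" not in t.columns or t["group"].isna().any():
        raise ValueError("every ROI needs a group assignment")
    rows = []
    for roi, sub in t.groupby("roi_id"):
        if sub.empty:
            warnings.warn(f"ROI {roi!r} has no cells; excluded")
            continue
        group = sub["group"].iloc[0]
        n = len(sub)
        for label, cnt in sub["phenotype"].value_counts().items():
            rows.append({"roi_id": roi, "group": group, "level": "phenotype",
                         "label": label, "percent": 100.0 * cnt / n})
        immune = sub[sub["phenotype"] == "immune"]
        for label, cnt in immune["immune_subtype"].value_counts().items():
            rows.append({"roi_id": roi, "group": group,
                         "level": "immune_subtype", "label": label,
                         "percent": 100.0 * cnt / n})
    per_roi = pd.DataFrame(rows)
    gm = (per_roi.groupby(["group", "level", "label"])["percent"]
          .mean().rename("mean_percent").reset_index())
    return AbundanceResult(per_roi=per_roi, group_means=gm)


def sidak_adjust(p: np.ndarray, m: int) -> np.ndarray:
    """Šídák correction for m comparisons: p_adj = 1 − (1 − p)^m."""
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** m


def compare_abundance(per_roi: pd.DataFrame, level: str = "phenotype",
                      alpha: float = 0.05) -> pd.DataFrame:
    """Two-way ANOVA (cluster × group) on per-ROI percentages with per-cluster
    Šídák-adjusted group contrasts.

    Exactly two groups are compared; each must contribute >= 2 ROIs. The
    per-cluster contrast uses the ANOVA residual mean square; adjusted
    p-values below ``alpha`` are flagged significant.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    d = per_roi[per_roi["level"] == level]
    # absent phenotype in an ROI = 0 percent, not missing
    full = (d.set_index(["roi_id", "group", "label"])["percent"]
            .unstack(fill_value=0.0).stack().rename("percent").reset_index())
    groups = sorted(full["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    n_roi = full.groupby("group")["roi_id"].nunique()
    if (n_roi < 2).any():
        raise ValueError(f"each group needs >= 2 ROIs: {n_roi.to_dict()}")

    fit = ols("percent ~ C(label) * C(group)", data=full).fit()
    mse = fit.mse_resid
    dof = fit.df_resid
    labels = sorted(full["label"].unique())
    m = len(labels)
    rows = []
    for lab in labels:
        sub = full[full["label"] == lab]
        a = sub.loc[sub["group"] == groups[0], "percent"]
        b = sub.loc[sub["group"] == groups[1], "percent"]
        se = np.sqrt(mse * (1 / len(a) + 1 / len(b)))
        tval = (a.mean() - b.mean()) / se if se > 0 else 0.0
        p = 2 * stats.t.sf(abs(tval), dof)
        rows.append({"label": lab,
                     f"mean_{groups[0]}": a.mean(),
                     f"mean_{groups[1]}": b.mean(),
                     "t": tval, "p": p})
    res = pd.DataFrame(rows)
    res["p_adj"] = sidak_adjust(res["p"].to_numpy(), m)
    res["significant"] = res["p_adj"] < alpha
    return res
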