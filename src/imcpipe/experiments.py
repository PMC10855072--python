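"""End-to-end reproduction workflows on synthetic data.

Each function builds its own inputs from the synthetic generator under the
pipeline's default study conditions, runs the relevant stages, and returns the
summary metrics. They back both the validation suite and the
``scripts/acceptance.py`` reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import panel as pn
from .phenotyping import phenotype_cells
from .preprocess import build_stack, remove_hot_pixels
from .segmentation import (compute_pixel_features, match_to_ground_truth,
                           predict_probability_maps, segment_cells,
                           train_pixel_classifier)
from .single_cell import qc_filter, quantify, transform_normalize
from .spatial import aggregate_scores, interaction_test_roi, neighbor_graph
from .synthetic import (TYPE_IMMUNE_SUBTYPE, TYPE_PHENOTYPE, LayoutSpec,
                        NoiseSpec, example_signatures, ground_truth_mask,
                        place_cells, render_roi, sample_cells,
                        scribbles_from_ground_truth, synthetic_panel)

NULL_TYPES = ("A", "B", "C", "D")


def _interaction_rois(layouts, seeds, n_perm, alpha, ring_width=2.0):
    results = []
    for spec, seed in zip(layouts, seeds):
        cells = place_cells(spec, seed=seed)
        mask = ground_truth_mask(cells, spec.image_size, ring_width=spec.ring_width)
        graph = neighbor_graph(mask, roi_id=f"roi{seed}")
        phenos = {c.mask_label: c.type for c in cells}
        results.append(interaction_test_roi(
            graph, phenos, n_perm=n_perm, alpha=alpha, seed=seed + 10_000,
            phenotype_order=list(spec.n_cells)))
    return results


def null_interaction_calibration(seed: int, n_rois: int = 20,
                                 n_cells_per_type: int = 100,
                                 image_size: tuple[int, int] = (600, 600),
                                 n_perm: int = 1000, alpha: float = 0.01) -> dict:
    """Complete spatial randomness with uniform types: the permutation test
    should stay silent. Returns the fraction of nonzero (pair, ROI) scores and
    the largest |ROI-averaged score|."""
    layouts = [LayoutSpec(mode="random", image_size=image_size,
                          n_cells={t: n_cells_per_type for t in NULL_TYPES})
               for _ in range(n_rois)]
    results = _interaction_rois(layouts, [seed + i for i in range(n_rois)],
                                n_perm, alpha)
    scores = np.stack([r.score for r in results])
    agg = aggregate_scores(results).to_numpy()
    return {
        "fraction_nonzero": float(np.nanmean(scores != 0)),
        "max_abs_aggregate": float(np.nanmax(np.abs(agg))),
        "n_rois": n_rois,
        "n_cells": int(n_cells_per_type * len(NULL_TYPES)),
    }


def attraction_recovery(seed: int, n_rois: int = 10, n_cells_per_type: int = 80,
                        max_distance: float = 10.0,
                        image_size: tuple[int, int] = (800, 800),
                        n_perm: int = 1000, alpha: float = 0.01) -> dict:
    """Planted A–B attraction (each B within ``max_distance`` µm of an A):
    the ROI-averaged A→B score should saturate near +1."""
    layouts = [LayoutSpec(mode="paired_attraction", image_size=image_size,
                          n_cells={t: n_cells_per_type for t in NULL_TYPES},
                          attraction=[("A", "B", max_distance)],
                          nucleus_radius=3.0, ring_width=1.0,
                          min_center_distance=8.0)
               for _ in range(n_rois)]
    results = _interaction_rois(layouts, [seed + i for i in range(n_rois)],
                                n_perm, alpha)
    agg = aggregate_scores(results)
    return {"score_a_to_b": float(agg.loc["A", "B"]),
            "score_b_to_a": float(agg.loc["B", "A"]),
            "n_rois": n_rois}


def segregation_recovery(seed: int, n_rois: int = 10,
                         n_cells_per_type: int = 100,
                         image_size: tuple[int, int] = (600, 600),
                         band_width: float = 120.0,
                         n_perm: int = 1000, alpha: float = 0.01) -> dict:
    """Planted exclusion (A confined to the core, B to the margin band):
    the ROI-averaged A→B score should saturate near −1."""
    layouts = [LayoutSpec(mode="core_margin", image_size=image_size,
                          n_cells={t: n_cells_per_type for t in NULL_TYPES},
                          core_types=("A",), margin_types=("B",),
                          margin_band_width=band_width)
               for _ in range(n_rois)]
    results = _interaction_rois(layouts, [seed + i for i in range(n_rois)],
                                n_perm, alpha)
    agg = aggregate_scores(results)
    return {"score_a_to_b": float(agg.loc["A", "B"]),
            "score_b_to_a": float(agg.loc["B", "A"]),
            "n_rois": n_rois}


SEGMENTATION_TYPES = ("tumor", "stromal", "macrophage", "cd8_t")


def segmentation_recovery(seed: int, noise: bool, n_cells: int = 300,
                          image_size: tuple[int, int] = (500, 500),
                          iou_threshold: float = 0.5) -> dict:
    """Full segmentation pass (features → forest → probability maps → masks)
    on one synthetic ROI; recall/precision of 1:1 ground-truth matching at the
    IoU threshold."""
    types = SEGMENTATION_TYPES
    sigs = example_signatures(cell_types=list(types))
    spec = LayoutSpec(mode="random", image_size=image_size,
                      n_cells={t: n_cells // len(types) for t in types})
    cells = place_cells(spec, seed=seed)
    nspec = NoiseSpec(seed=seed) if noise else NoiseSpec.noiseless(seed=seed)
    image, true_mask = render_roi(cells, sigs, nspec, spec.image_size)
    stack = build_stack(image, synthetic_panel(sigs), "segmentation")
    feats = compute_pixel_features(stack.data)
    scribbles = scribbles_from_ground_truth(cells, stack.shape)
    clf = train_pixel_classifier(feats, scribbles, seed=seed)
    probs = predict_probability_maps(clf, feats)
    pred = segment_cells(probs)
    m = match_to_ground_truth(pred, true_mask, iou_threshold=iou_threshold)
    return {"recall": m["recall"], "precision": m["precision"],
            "n_true": m["n_true"], "n_pred": m["n_pred"],
            "oob_accuracy": float(clf.oob_score_),
            "image": image, "true_mask": true_mask, "pred_mask": pred,
            "cells": cells}


CLUSTERING_TYPES = ("tumor", "stromal", "endothelial", "lymphatic",
                    "macrophage", "cd8_t")


def clustering_recovery(seed: int, n_cells: int = 5000, k: int = 100) -> dict:
    """Six well-separated cell types at clustering scale: Phenograph-style
    clustering plus rule annotation should recover the planted phenotypes."""
    from sklearn.metrics import adjusted_rand_score

    types = CLUSTERING_TYPES
    sigs = example_signatures(cell_types=list(types),
                              markers=pn.ORTHOTOPIC_CLUSTERING_MARKERS)
    table = sample_cells(sigs, {t: n_cells // len(types) for t in types},
                         seed=seed)
    table["roi_id"] = "roi0"
    table["area_um2"] = 110.0
    table, report = qc_filter(table, clustering_markers=list(sigs.markers))
    table = transform_normalize(table, markers=list(sigs.markers))
    ann, result = phenotype_cells(table, list(sigs.markers), seed=seed, k=k)

    truth = (ann["true_type"].map(TYPE_PHENOTYPE).fillna("") + "/" +
             ann["true_type"].map(TYPE_IMMUNE_SUBTYPE).fillna(""))
    pred = (ann["phenotype"].fillna("") + "/" + ann["immune_subtype"].fillna(""))
    return {
        "annotation_accuracy": float((pred == truth).mean()),
        "ari": float(adjusted_rand_score(ann["true_type"], pred)),
        "n_cells": len(ann),
        "n_clusters": int(len(result.annotation)),
        "qc_fraction_discarded": report["fraction_discarded"],
    }


def qc_discard_on_default_run(seed: int, n_cells: int = 240,
                              image_size: tuple[int, int] = (450, 450)) -> dict:
    """Render a default-noise ROI over the full panel, quantify the cells and
    apply the three exclusion rules; the discarded fraction should stay within
    the expected ≤ 2%."""
    types = CLUSTERING_TYPES
    sigs = example_signatures(cell_types=list(types))
    spec = LayoutSpec(mode="random", image_size=image_size,
                      n_cells={t: n_cells // len(types) for t in types})
    cells = place_cells(spec, seed=seed)
    image, mask = render_roi(cells, sigs, NoiseSpec(seed=seed), spec.image_size)
    clean = image.data.copy()
    for i in range(clean.shape[0]):
        clean[i] = remove_hot_pixels(clean[i])
    from .image import MultiplexImage

    table = quantify(mask, MultiplexImage(roi_id="roi0",
                                          channels=image.channels, data=clean))
    _, report = qc_filter(table,
                          clustering_markers=pn.ORTHOTOPIC_CLUSTERING_MARKERS)
    return report
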