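# imcpipe

A single-cell analysis pipeline for imaging mass cytometry (IMC) of tissue,
built around the tumor-microenvironment profiling of murine pancreatic ductal
adenocarcinoma (PDAC). IMC ablates a tissue section with a UV laser at
~1 µm²/pixel and reads one channel per metal-isotope-tagged antibody, yielding
a multichannel intensity image ("dual counts") per region of interest (ROI).
`imcpipe` turns such images into annotated single cells and spatial
interaction statistics:

1. **Preprocessing** — hot-pixel removal by local-median replacement (disk
   radius 2 px, threshold 50 dual counts), per-channel scaling to the 99th
   intensity percentile (floor of 10 dual counts, clipped to [0, 1]), optional
   per-channel low-intensity thresholds.
2. **Segmentation** — a random-forest pixel classifier trained on sparse
   scribbles over multi-scale features produces nuclei / cytoplasm /
   background probability maps; nuclei are thresholded, split by seeded
   watershed on the distance transform, and expanded through the cytoplasm
   posterior into cell masks.
3. **Quantification + QC** — per-cell mean marker intensity, area and
   centroid; cells are excluded if area > 500 µm², mean intensity > 2 in all
   markers, or < 0.01 in all clustering markers.
4. **Phenotyping** — intensities are asinh-rescaled and normalized between
   the 1st and 99th percentile; cells are clustered Phenograph-style (Jaccard
   kNN graph, k = 100, Louvain modularity) and clusters are annotated into six
   phenotype classes (epithelial/tumor, stromal, immune, endothelial,
   lymphatic, other) plus six immune subtypes by lineage-marker rules
   (CD31 → endothelial, LYVE-1 → lymphatic, CD45 → immune, F4/80 →
   monocyte/macrophage, CD3+CD8 → CD8 T, ...). Per-ROI abundances are compared
   between groups by two-way ANOVA with Šídák-adjusted contrasts,
   p_adj = 1 − (1 − p)^m.
5. **Spatial neighborhood analysis** — cells are neighbors when their
   border-to-border distance is < 30 µm. For each ordered phenotype pair
   (A, B), the mean number of B neighbors per A cell is compared to a null
   built from 1000 permutations of the phenotype labels over the fixed graph;
   p < 0.01 enrichment scores +1, depletion −1, otherwise 0, averaged over
   ROIs into an interaction heatmap matrix.

Because no public IMC dataset accompanies this design, the package ships a
first-class **synthetic generator** (`imcpipe.synthetic`): multichannel ROIs
with disk-nucleus/ring-cytoplasm cells, type-specific lognormal marker
signatures over the 28-marker PDAC antibody panel plus a DNA channel, Poisson
counting noise, isolated hot pixels, and three layout modes — complete spatial
randomness, tumor-core vs stromal-margin architecture, and planted
attraction between cell-type pairs — with full ground truth for every stage.

## Worked example

```python
import numpy as np
import imcpipe as ip

# 1. simulate a 500x500 µm ROI with four planted cell types
sigs = ip.example_signatures(cell_types=["tumor", "stromal", "macrophage", "cd8_t"])
layout = ip.LayoutSpec(mode="random", image_size=(500, 500),
                       n_cells={t: 75 for t in sigs.cell_types})
cells = ip.place_cells(layout, seed=7)
image, truth = ip.render_roi(cells, sigs, ip.NoiseSpec(seed=7), layout.image_size)
panel = ip.synthetic_panel(sigs)

# 2. preprocess + segment
stack = ip.build_stack(image, panel, "segmentation")
feats = ip.compute_pixel_features(stack.data)
scribbles = ip.scribbles_from_ground_truth(cells, stack.shape)
clf = ip.train_pixel_classifier(feats, scribbles, seed=7)
probs = ip.predict_probability_maps(clf, feats)
mask = ip.segment_cells(probs)
match = ip.match_to_ground_truth(mask, truth)
print(f"segmented {mask.max()} cells, recall at IoU>=0.5: {match['recall']:.3f}")

# 3. quantify, QC, normalize, cluster, annotate
clean = np.stack([ip.remove_hot_pixels(c) for c in image.data])
table = ip.quantify(mask, ip.MultiplexImage("roi0", image.channels, clean))
table, report = ip.qc_filter(table, ip.ORTHOTOPIC_CLUSTERING_MARKERS)
print(f"QC discarded {report['n_discarded']}/{report['n_total']} cells")
table = ip.transform_normalize(table, markers=ip.ORTHOTOPIC_CLUSTERING_MARKERS)
table, result = ip.phenotype_cells(table, ip.ORTHOTOPIC_CLUSTERING_MARKERS, seed=7, k=30)
print(result.annotation)
```

Output:

```
segmented 300 cells, recall at IoU>=0.5: 1.000
QC discarded 0/300 cells
                   phenotype   immune_subtype
cluster_id
0                     immune            CD8 T
1           epithelial/tumor             None
2                    stromal             None
3                     immune  mono/macrophage
```

All 300 planted cells are recovered at IoU ≥ 0.5, none are lost to QC, and
Louvain finds exactly the four planted populations, annotated to the correct
phenotype class and immune subtype. The spatial score matrix for this ROI
(`ip.interaction_test_roi` on `ip.neighbor_graph(mask)`) is all zeros —
correct, since the `random` layout plants no attraction or avoidance.

The same stages are exposed on the command line:

```sh
imcpipe simulate --layout random --n-cells 300 --size 500 --seed 7 --out roi/
imcpipe preprocess --in roi/image.tiff --panel roi/panel.csv --role segmentation --out clean.tiff
imcpipe segment --fixture roi/ --out mask.tiff
imcpipe quantify --mask mask.tiff --image roi/image.tiff --panel roi/panel.csv --out cells.csv
imcpipe cluster --cells cells.csv --panel roi/panel.csv --k 100 --seed 7 --out clustered/
imcpipe spatial --mask mask.tiff --cells clustered/cells_annotated.csv --out scores.csv
```

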