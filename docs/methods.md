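# Methods

This note documents the models and numerical choices behind `imcpipe`, module
by module, and what the synthetic benchmarks do and do not demonstrate.

## Synthetic data model

The generator emulates imaging mass cytometry of tissue at 1 µm²/pixel (all
µm parameters convert 1:1 to pixels; this convention is used everywhere).

**Cells.** A cell is a disk nucleus (default radius 4 µm) with an annular
cytoplasm ring (default width 2 µm), giving ~113 µm² footprints — realistic
for murine tissue and comfortably below the 500 µm² QC cutoff. Placement is a
hard-core point process: centers are rejection-sampled until all pairwise
distances exceed `min_center_distance` (default 15 µm; the constructor
enforces ≥ 2× nucleus radius). Three layout modes:

- `random` — uniform placement; with uniform type assignment this is the
  complete-spatial-randomness null used to calibrate the interaction test.
- `core_margin` — listed margin types are confined to a band along the image
  border, core types to the interior, emulating a dense tumor core wrapped in
  stroma-rich margin; also used to plant spatial avoidance.
- `paired_attraction` — each B cell of an (A, B, d) pair is placed within
  d µm of a random A cell (and at least `min_center_distance` away), planting
  a known enrichment. For attraction distances below the default hard-core
  radius the smaller nucleus (3 µm) and ring (1 µm) are used so the annulus
  [min_center_distance, d] is samplable.

**Intensities.** Per cell and marker one lognormal value is drawn,
`mean * exp(sigma * z)` with z ~ N(0, 1) — multiplicative biological
variation parameterized by the median so that dispersion → 0 reproduces the
signature mean exactly — and painted over the whole footprint; the DNA
channel (iridium intercalator) covers only the nucleus disk. Non-cell pixels
carry a uniform background (default 0.5 dual counts). Optional Poisson
resampling models ion-counting noise; hot pixels are single pixels set to a
large amplitude (default 2000 dual counts) at a given rate, constrained to
pairwise distance > 2 px so that a radius-2 median filter can always repair
them — matching their physical origin as isolated detector events. The
reference signature matrix gives each of ten cell types its lineage markers
(tumor: ZO-1/CK19/E-cadherin/PanCK; stromal: αSMA/PDGFRβ/Desmin/Collagen I;
endothelial: CD31/Collagen IV; lymphatic: LYVE-1; immune subtypes: CD45 plus
F4/80, CD103, Ly6G, CD3/CD4, CD3/CD8 or B220) at 10–25 dual counts over a
0.3 baseline, with lognormal sigma 0.35. No quantitative intensity
distributions are published for the reference data, so these defaults were
chosen once for plausibility (clear positive populations at realistic count
levels), not fitted to anything.

**What the generator does not model:** channel spillover between metals,
tissue autofluorescence, section-thickness (3-D) effects, irregular cell
shapes, intensity gradients within cells, or spatially varying background.
Passing benchmarks on this substrate therefore demonstrates correctness of
the algorithms under their stated assumptions, not performance on real
tissue, where segmentation and annotation are substantially harder.

## Preprocessing

Per channel, in fixed order:

1. **Hot-pixel removal** — for each pixel the median over the Euclidean disk
   of radius 2 px (clipped at image edges) is computed; a pixel more than 50
   dual counts above its local median is replaced by that median. Only bright
   outliers are ever touched. The disk neighborhood and the bright-only rule
   mirror the standard ImageJ outlier-removal behavior. The operation is
   idempotent for isolated spikes; a repaired pixel adjacent to a bright
   structure edge can occasionally shift a neighbor's median enough to
   trigger one more repair on a second pass (observed at ~1 in 10⁵ pixels).
2. **p99 normalization** — divide by max(99th percentile, 10 dual counts) and
   clip to [0, 1]. The percentile is taken over all pixels including zeros
   (reproducible without a masking convention); the floor keeps near-empty
   channels from amplifying noise. Whether values above the divisor should
   clip or exceed 1 was an open choice; clipping was adopted.
3. **Low-intensity threshold** — values below a per-channel, visually tuned
   threshold (default 0) are zeroed.

## Segmentation

Pixel features are computed per channel at scales σ ∈ {1, 2, 4} px with
reflection padding: Gaussian smoothing, Gaussian gradient magnitude,
Laplacian of Gaussian, and both structure-tensor eigenvalues — 5 kinds ×
3 scales per channel (the σ = 1 smoothing stands in for the raw value).
A random forest (100 trees, fixed seed, out-of-bag accuracy reported) is
trained on sparse scribbles with three classes — nuclei, cytoplasm,
background. On synthetic data the scribbles are derived from ground truth:
eroded nucleus disks, the outer cytoplasm ring, and background pixels more
than 2 µm from any cell. The background margin matters: training background
only far from cells leaves the near-cell halo unlabeled and biases the
background posterior outward, inflating the segmented cells.

Mask creation: nucleus foreground = nuclei posterior ≥ 0.5 (0.5 is the
symmetric, scale-free choice for a 3-class posterior); objects under
10 µm² dropped; touching nuclei split by seeded watershed on the negated
distance transform, seeds = regional maxima of the σ = 1-smoothed distance
map at ≥ 2 px separation (the smoothing breaks plateau ties); each nucleus
expanded by watershed on (1 − cytoplasm posterior), restricted to pixels
with background posterior < 0.5 and within 5 µm of a nucleus. The 5 µm bound
prevents unbounded bleed into sparse regions. Labels are renumbered
consecutively so mask ↔ table joins are stable. Empty foreground yields an
empty mask with a warning, not an error.

Recovery is evaluated by 1:1 matching at IoU ≥ 0.5 (at that threshold
matches are necessarily unique). On 300-cell synthetic ROIs recall is 1.00
both noise-free and with default Poisson + hot-pixel noise, against target
floors of 0.95 and 0.90.

## Quantification, QC, normalization

Mean raw (hot-pixel-removed) intensity, area (pixel count × pixel area) and
centroid per cell, via `skimage.regionprops`. The three exclusion rules —
area > 500 µm², mean > 2 dual counts in *all* markers simultaneously, mean
< 0.01 in *all* clustering markers simultaneously — remove debris and
segmentation artifacts; on default synthetic runs they discard 0% (≤ 2%
expected). Both intensity rules are applied on the raw dual-count scale,
where the constants 2 and 0.01 are meaningful; the thresholds are
configurable since the conjunction reading ("all markers", chosen here) and
the scale of the 0.01 rule are reconstruction choices. A warning (not an
error) fires when more than 2% of cells are discarded.

Normalization: y = asinh(x / cofactor) with cofactor 1 (no cofactor is
conventionally fixed for IMC; 5 is offered as the cytometry alternative),
then per marker min-max over the pooled 1st–99th percentile of y, clipped to
[0, 1]. Pooling is over all cells in the table — all ROIs of a model are
normalized jointly, matching the joint clustering design. The transform is
strictly monotone between the clip points; a constant marker maps to 0.

## Phenotyping

The kNN graph uses Euclidean distance on the normalized clustering markers,
k = 100, self excluded, ties broken by index; undirected edges carry Jaccard
weights |N(i) ∩ N(j)| / |N(i) ∪ N(j)| over the k-neighborhoods, zero-weight
edges dropped. Louvain modularity optimization (igraph multilevel, seeded)
is the default, matching classic Phenograph behavior; Leiden is available
via `method="leiden"`. UMAP is for visualization only — no downstream step
consumes the embedding.

Annotation operates on the cluster × marker mean matrix, min-max normalized
per row (z-scoring is available; "normalized per row" admits both, min-max
keeps the [0, 1] interpretation). Each class scores the mean of its lineage
markers' row-normalized values; the arg-max class is assigned if its score
reaches `min_score` (default 0.5 — a cluster should express its lineage
markers at least halfway up its own dynamic range), else "other". Ties go to
the earlier rule, specific before broad (endothelial, lymphatic, immune,
stromal, epithelial/tumor). Immune clusters are sub-typed the same way.
Clusters under 0.5% of cells fall to "other". Rules referencing markers
absent from a clustering panel are either an error (strict API) or trimmed
via `restrict_rules` — e.g. the 19-marker orthotopic panel identifies the
tumor class by ZO-1 alone.

On six well-separated synthetic types (n ≈ 5000, k = 100) clustering plus
annotation recovers the planted phenotype for 100% of cells (ARI 1.0),
against floors of 95% and 0.9. Note that modularity optimization oversplits
low-dimensional geometric graphs (two 2-D Gaussian blobs yield ~6
communities); in marker-space dimensionality (10–19) recovery is exact.

Abundance: percent of each ROI's cells per phenotype (sums to 100) and per
immune subtype (relative to all ROI cells). Group comparison: two-way ANOVA
(cluster × group with interaction) on per-ROI percentages, absent phenotypes
counted as 0%; per-cluster two-group contrasts use the ANOVA residual mean
square, and p-values are Šídák-adjusted with m = number of clusters,
significance at p_adj < 0.05. Under a simulated null the per-cluster
false-positive rate stays below α plus Monte Carlo slack.

## Spatial neighborhood analysis

Cell boundaries are pixels 4-adjacent to a different label or the image
edge. Two cells are neighbors when the minimum distance between their
boundary pixels is strictly less than 30 µm; a k-d tree over boundary pixels
makes this exact (verified against the brute-force all-pairs oracle on
50 random fixtures). Distances are 2-D — sections are single planes here,
unlike 3-D-capable measurement plugins.

For ordered pair (A, B) the statistic is the mean B-neighbor count per
A cell; directed statistics are kept without symmetrization, following the
histoCAT-style formulation, so the score matrix is generally asymmetric.
The null permutes phenotype labels over nodes (graph fixed) n = 1000 times;
p_enrich = (1 + #{null ≥ obs}) / (n + 1) and symmetrically for depletion —
the add-one convention keeps p > 0 and ties count toward the null
(conservative). Score: +1 if p_enrich < 0.01, −1 if p_deplete < 0.01, else
0. Pairs whose A or B phenotype is absent from an ROI are undefined (NaN)
and excluded from the ROI average rather than imputed 0; a pair undefined
everywhere is reported missing. The permutation loop is an O(edges) bincount
over ordered phenotype-pair codes per permutation — numerically identical to
the per-pair definition and verified against exhaustive enumeration of all
label permutations on 6-node toys.

Calibration and recovery under default conditions (seeded): 20 CSR ROIs of
400 cells / 4 types give a nonzero-score fraction of ~0.3–1.6% (bound 3%)
and |ROI-averaged score| ≤ 0.05 per pair; 10 ROIs with planted 10 µm A–B
attraction give an averaged A→B score of +1.0 (floor +0.9); planted
core/margin segregation gives −1.0 (ceiling −0.9).

## Benchmark problem sizes

The validation suite and `scripts/acceptance.py` use: 20 calibration ROIs of
600×600 µm with 400 cells each; 10 ROIs per planted-interaction scenario;
one 500×500 µm, 300-cell ROI per segmentation condition; 4998 cells for
clustering recovery; 240 cells for the QC run — sizes at which every metric
is stable across seeds while a full run stays in the minutes range on one
CPU. All randomness flows from explicit integer seeds; identical seeds give
bit-identical images, masks, p-values and scores.

## Known limitations

- The CellProfiler-equivalent mask-creation chain is a faithful generic
  reconstruction (threshold, declump, bounded expansion); the original
  module settings are not published.
- Interactive classifier training is replaced by programmatic scribbles;
  applying the segmentation stage to real images requires supplying real
  scribbles or probability maps.
- No spillover compensation, MCD parsing, shape descriptors beyond area, or
  spatial statistics beyond pairwise neighborhood scores.
- The annotation rule set resolves ties by rule order; genuinely
  mixed-lineage clusters fall to whichever listed class scores highest, and
  clusters expressing only part of a multi-marker lineage signature can fall
  to "other" at the default `min_score`.
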