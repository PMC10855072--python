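"""Pixel classification and single-cell segmentation.

A random forest trained on sparse scribbles over multi-scale image features
produces per-pixel posteriors for the three classes nuclei / cytoplasm /
background; nuclei are thresholded, split by seeded watershed on the distance
transform, and expanded through the cytoplasm posterior to form cell masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max, structure_tensor, structure_tensor_eigenvalues
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import relabel_sequential, watershed
from sklearn.ensemble import RandomForestClassifier

CLASS_NAMES = ("nuclei", "cytoplasm", "background")
FEATURE_SCALES = (1.0, 2.0, 4.0)
FEATURE_KINDS = ("gaussian", "gradient_magnitude", "laplacian_of_gaussian",
                 "structure_tensor_eig_max", "structure_tensor_eig_min")


@dataclass
class ProbabilityMaps:
    """Per-pixel class posteriors, (3, H, W); rows sum to 1."""

    data: np.ndarray
    classes: tuple[str, str, str] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != 3:
            raise ValueError("probability maps must be (3, H, W)")
        if not np.allclose(self.data.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("class probabilities must sum to 1 per pixel")

    @property
    def nuclei(self) -> np.ndarray:
        return self.data[0]

    @property
    def cytoplasm(self) -> np.ndarray:
        return self.data[1]

    @property
    def background(self) -> np.ndarray:
        return self.data[2]


def compute_pixel_features(stack: np.ndarray) -> np.ndarray:
    """Multi-scale per-pixel features, (H, W, channels x 5 kinds x 3 scales).

    Per channel and scale sigma in {1, 2, 4} px: Gaussian smoothing, Gaussian
    gradient magnitude, Laplacian of Gaussian, and the two structure-tensor
    eigenvalues. Borders use reflection padding. Deterministic.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] < 1 or stack.size == 0:
        raise ValueError("need at least one nonempty channel")
    feats = []
    for ch in stack:
        for s in FEATURE_SCALES:
            feats.append(ndi.gaussian_filter(ch, s, mode="reflect"))
            feats.append(ndi.gaussian_gradient_magnitude(ch, s, mode="reflect"))
            feats.append(ndi.gaussian_laplace(ch, s, mode="reflect"))
            t = structure_tensor(ch, sigma=s, mode="reflect")
            eig = structure_tensor_eigenvalues(t)
            feats.append(eig[0])
            feats.append(eig[1])
    return np.stack(feats, axis=-1).astype(np.float32)


def train_pixel_classifier(features: np.ndarray, scribbles: np.ndarray, seed: int,
                           n_estimators: int = 100) -> RandomForestClassifier:
    """Fit a random forest on scribble-labeled pixels.

    ``scribbles`` is an (H, W) image with 0 = unlabeled, 1 = nuclei,
    2 = cytoplasm, 3 = background; all three classes must be present (>= 50
    pixels each recommended). The fitted forest reports its out-of-bag
    accuracy as ``oob_score_``.
    """
    features = np.asarray(features)
    scribbles = np.asarray(scribbles)
    if features.shape[:2] != scribbles.shape:
        raise ValueError("features and scribbles disagree in shape")
    present = set(np.unique(scribbles)) - {0}
    if present != {1, 2, 3}:
        missing = [CLASS_NAMES[c - 1] for c in (1, 2, 3) if c not in present]
        raise ValueError(f"scribbles missing class(es): {missing}")
    sel = scribbles > 0
    counts = np.bincount(scribbles[sel], minlength=4)[1:]
    if counts.min() < 50:
        warnings.warn(f"fewer than 50 scribble pixels for some class: {counts}")
    clf = RandomForestClassifier(n_estimators=n_estimators, oob_score=True,
                                 random_state=seed, n_jobs=1)
    clf.fit(features[sel], scribbles[sel])
    return clf


def predict_probability_maps(clf: RandomForestClassifier,
                             features: np.ndarray) -> ProbabilityMaps:
    """Per-pixel class posteriors from a fitted classifier."""
    features = np.asarray(features)
    if features.ndim != 3 or features.shape[2] != clf.n_features_in_:
        raise ValueError(
            f"feature layout {features.shape} does not match training "
            f"({clf.n_features_in_} features)")
    h, w, f = features.shape
    proba = clf.predict_proba(features.reshape(-1, f))
    # columns follow clf.classes_ = [1, 2, 3]
    order = np.argsort(clf.classes_)
    proba = proba[:, order]
    return ProbabilityMaps(proba.T.reshape(3, h, w))


def segment_cells(probmaps: ProbabilityMaps, min_nucleus_area: float = 10.0,
                  max_expand: float = 5.0, pixel_size: float = 1.0) -> np.ndarray:
    """Label mask from probability maps.

    Nucleus foreground is the >= 0.5 nuclei posterior; objects below
    ``min_nucleus_area`` µm² are dropped; touching nuclei are split by seeded
    watershed on the negated distance transform (regional maxima >= 2 px
    apart); each nucleus is then expanded by watershed on (1 − cytoplasm
    posterior), limited to pixels with background posterior < 0.5 and within
    ``max_expand`` µm of the nucleus. Labels are consecutive from 1.
    """
    min_px = max(1, int(round(min_nucleus_area / pixel_size ** 2)))
    fg = probmaps.nuclei >= 0.5
    if min_px > 1:
        fg = remove_small_objects(fg, max_size=min_px - 1)
    if not fg.any():
        warnings.warn("no nucleus foreground; returning empty mask")
        return np.zeros(fg.shape, dtype=np.int32)

    dist = ndi.distance_transform_edt(fg)
    smooth = ndi.gaussian_filter(dist, 1.0)  # break plateau ties
    coords = peak_local_max(smooth, min_distance=2, labels=fg,
                            exclude_border=False)
    peaks = np.zeros(fg.shape, dtype=bool)
    peaks[tuple(coords.T)] = True
    markers, _ = ndi.label(peaks)
    if markers.max() == 0:  # degenerate: use connected components
        markers, _ = ndi.label(fg)
    nuclei = watershed(-dist, markers, mask=fg)

    dist_out = ndi.distance_transform_edt(nuclei == 0)
    allowed = ((probmaps.background < 0.5) &
               (dist_out <= max_expand / pixel_size)) | (nuclei > 0)
    cells = watershed(1.0 - probmaps.cytoplasm, nuclei, mask=allowed)
    cells, _, _ = relabel_sequential(cells)
    return cells.astype(np.int32)


def match_to_ground_truth(pred_mask: np.ndarray, true_mask: np.ndarray,
                          iou_threshold: float = 0.5) -> dict:
    """1:1 matching of predicted to ground-truth cells at an IoU threshold.

    At IoU >= 0.5 matches are necessarily unique, so matching is simply the
    set of (true, pred) pairs whose intersection-over-union clears the
    threshold. Returns recall (fraction of true cells matched), precision and
    the match list.
    """
    from scipy import sparse

    pred = np.asarray(pred_mask).ravel()
    true = np.asarray(true_mask).ravel()
    both = (pred > 0) | (true > 0)
    pairs = sparse.coo_matrix(
        (np.ones(both.sum()), (true[both], pred[both]))).tocsr()
    true_area = np.bincount(true, minlength=pairs.shape[0])
    pred_area = np.bincount(pred, minlength=pairs.shape[1])
    inter = pairs.tocoo()
    matches = []
    for t, p, n in zip(inter.row, inter.col, inter.data):
        if t == 0 or p == 0:
            continue
        iou = n / (true_area[t] + pred_area[p] - n)
        if iou >= iou_threshold:
            matches.append((int(t), int(p), float(iou)))
    n_true = int((np.unique(true) > 0).sum())
    n_pred = int((np.unique(pred) > 0).sum())
    return {
        "matches": matches,
        "recall": len(matches) / n_true if n_true else 0.0,
        "precision": len(matches) / n_pred if n_pred else 0.0,
        "n_true": n_true,
        "n_pred": n_pred,
    }
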