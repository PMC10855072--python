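"""Synthetic IMC-like ROI generator with known ground truth.

Emulates laser-ablation imaging mass cytometry data at 1 µm²/pixel: cells are
disk nuclei (DNA channel) with an annular cytoplasm ring, painted with
cell-type-specific lognormal marker intensities over a low uniform background,
optionally degraded by Poisson counting noise and isolated hot pixels. Three
layout modes reproduce the tissue architectures of interest: complete spatial
randomness (the calibration null), a dense core surrounded by a stroma-rich
margin band, and planted attraction between a pair of cell types (for
neighborhood-score recovery).

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; identical seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .image import MultiplexImage, read_image, read_mask, write_image, write_mask
from .panel import DNA_CHANNEL, PANEL_MARKERS, make_panel, read_panel, write_panel

# --------------------------------------------------------------------------- #
# domain types


@dataclass
class GroundTruth:
    """One planted cell: identity, position (µm) and mask label."""

    cell_id: int
    type: str
    centroid: tuple[float, float]  # (x, y) µm
    nucleus_radius: float
    mask_label: int


@dataclass
class SignatureMatrix:
    """Per-(cell type, marker) lognormal intensity model, in dual counts.

    ``mean`` is the median of the per-cell lognormal draw (so a dispersion of 0
    reproduces the mean exactly); ``dispersion`` is the lognormal sigma.
    """

    cell_types: list[str]
    markers: list[str]
    mean: np.ndarray        # (T, M) ≥ 0
    dispersion: np.ndarray  # (T, M) > 0
    background: float = 0.3  # baseline tissue level entered for non-expressed markers

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.dispersion = np.broadcast_to(
            np.asarray(self.dispersion, dtype=float), self.mean.shape
        ).copy()
        if self.mean.shape != (len(self.cell_types), len(self.markers)):
            raise ValueError("mean must be (types, markers)")
        if (self.mean < 0).any():
            raise ValueError("signature means must be nonnegative")
        if (self.dispersion <= 0).any():
            raise ValueError("dispersions must be positive")
        if not (self.mean.max(axis=1) > self.background).all():
            raise ValueError("every type needs a marker above the background level")

    def row(self, cell_type: str) -> int:
        try:
            return self.cell_types.index(cell_type)
        except ValueError:
            raise KeyError(f"unknown cell type {cell_type!r}") from None


@dataclass
class LayoutSpec:
    """Where and how many cells to place.

    ``mode`` is one of ``random`` (hard-core CSR, the permutation-test null),
    ``core_margin`` (``margin_types`` confined to a band of ``margin_band_width``
    µm along the image border, ``core_types`` to the interior) or
    ``paired_attraction`` (each B of an ``attraction`` pair placed within
    ``max_distance`` µm of some A).
    """

    mode: str
    image_size: tuple[int, int]  # (H, W) µm
    n_cells: dict[str, int]
    min_center_distance: float = 15.0
    attraction: list[tuple[str, str, float]] = field(default_factory=list)
    margin_band_width: float = 100.0
    core_types: tuple[str, ...] = ()
    margin_types: tuple[str, ...] = ()
    nucleus_radius: float = 4.0
    ring_width: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in ("random", "core_margin", "paired_attraction"):
            raise ValueError(f"unknown layout mode {self.mode!r}")
        if min(self.image_size) <= 0:
            raise ValueError("image_size must be positive")
        if self.min_center_distance < 2 * self.nucleus_radius:
            raise ValueError("min_center_distance must be >= 2 x nucleus radius")
        if self.mode == "paired_attraction":
            for a, b, d in self.attraction:
                if d < self.min_center_distance:
                    raise ValueError(
                        "attraction max_distance < min_center_distance: unplaceable"
                    )


@dataclass
class NoiseSpec:
    """Acquisition noise: uniform background, Poisson counting noise and
    isolated hot pixels (single bright detector-noise pixels, never adjacent,
    so a radius-2 median can always repair them)."""

    background_mean: float = 0.5
    poisson: bool = True
    hot_pixel_rate: float = 1e-3
    hot_pixel_amplitude: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.hot_pixel_rate <= 0.01:
            raise ValueError("hot_pixel_rate must be in [0, 0.01]")

    @classmethod
    def noiseless(cls, background_mean: float = 0.5, seed: int = 0) -> "NoiseSpec":
        return cls(background_mean=background_mean, poisson=False,
                   hot_pixel_rate=0.0, seed=seed)


class PlacementError(RuntimeError):
    pass


# --------------------------------------------------------------------------- #
# reference signatures

#: phenotype class of each example cell type (immune subtypes map to "immune")
TYPE_PHENOTYPE: dict[str, str] = {
    "tumor": "epithelial/tumor",
    "stromal": "stromal",
    "endothelial": "endothelial",
    "lymphatic": "lymphatic",
    "macrophage": "immune",
    "dendritic": "immune",
    "neutrophil": "immune",
    "cd4_t": "immune",
    "cd8_t": "immune",
    "b_cell": "immune",
}

#: immune subtype of the immune example types
TYPE_IMMUNE_SUBTYPE: dict[str, str] = {
    "macrophage": "mono/macrophage",
    "dendritic": "dendritic",
    "neutrophil": "neutrophil",
    "cd4_t": "CD4 T",
    "cd8_t": "CD8 T",
    "b_cell": "B",
}

_SIGNATURE_DEFS: dict[str, dict[str, float]] = {
    "tumor": {"ZO-1": 25, "CK19": 18, "E-cadherin": 18, "PanCK": 12,
              "PDGFRa": 6, "PDGFRb": 6},
    "stromal": {"aSMA": 22, "PDGFRb": 18, "Desmin": 16, "Collagen I": 20,
                "Vimentin": 8, "CD44": 8},
    "endothelial": {"CD31": 22, "Collagen IV": 16, "PV1": 10},
    "lymphatic": {"Lyve-1": 24, "Vimentin": 6},
    "macrophage": {"CD45": 18, "F4/80": 20, "CD11b": 14, "CD206": 6},
    "dendritic": {"CD45": 18, "CD103": 20, "MHC-II": 12},
    "neutrophil": {"CD45": 18, "Ly6G": 22, "CD11b": 12},
    "cd4_t": {"CD45": 18, "CD3": 20, "CD4": 18},
    "cd8_t": {"CD45": 18, "CD3": 20, "CD8": 18},
    "b_cell": {"CD45": 18, "B220": 22},
}


def example_signatures(cell_types: list[str] | None = None,
                       markers: list[str] | None = None,
                       dispersion: float = 0.35,
                       background: float = 0.3) -> SignatureMatrix:
    """Reference signature matrix over the PDAC panel.

    Each cell type expresses its lineage markers (e.g. tumor: ZO-1/CK19/
    E-cadherin/PanCK; stromal: aSMA/PDGFRb/Desmin/Collagen I) well above a
    uniform tissue background, mirroring the marker/cluster correspondence the
    annotation rules rely on.
    """
    if cell_types is None:
        cell_types = list(_SIGNATURE_DEFS)
    unknown = set(cell_types) - set(_SIGNATURE_DEFS)
    if unknown:
        raise KeyError(f"no reference signature for {sorted(unknown)}")
    if markers is None:
        markers = [m for m, _ in PANEL_MARKERS]
    mean = np.full((len(cell_types), len(markers)), background, dtype=float)
    for i, t in enumerate(cell_types):
        for m, v in _SIGNATURE_DEFS[t].items():
            if m in markers:
                mean[i, markers.index(m)] = v
    return SignatureMatrix(cell_types=list(cell_types), markers=list(markers),
                           mean=mean, dispersion=np.full_like(mean, dispersion),
                           background=background)


# --------------------------------------------------------------------------- #
# cell placement


def _border_distance(x: np.ndarray, y: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    h, w = size
    return np.minimum(np.minimum(x, w - 1 - x), np.minimum(y, h - 1 - y))


def place_cells(layout: LayoutSpec, seed: int,
                max_attempts_per_cell: int = 10_000) -> list[GroundTruth]:
    """Hard-core placement of cells according to ``layout``.

    All pairwise center distances are >= ``min_center_distance``. Placement is
    sequential rejection sampling; a cell that cannot be placed within
    ``max_attempts_per_cell`` draws raises :class:`PlacementError` naming the
    density constraint.
    """
    rng = np.random.default_rng(seed)
    h, w = layout.image_size
    pad = layout.nucleus_radius + layout.ring_width  # keep footprints in bounds
    if w <= 2 * pad or h <= 2 * pad:
        raise ValueError("image too small for the cell footprint")

    attract_b = {b: (a, d) for a, b, d in layout.attraction} \
        if layout.mode == "paired_attraction" else {}
    order = sorted(layout.n_cells, key=lambda t: t in attract_b)  # anchors first

    pts: list[tuple[float, float]] = []
    cells: list[GroundTruth] = []

    def _ok(x: float, y: float) -> bool:
        if not pts:
            return True
        arr = np.asarray(pts)
        d2 = (arr[:, 0] - x) ** 2 + (arr[:, 1] - y) ** 2
        return bool(d2.min() >= layout.min_center_distance ** 2)

    def _region_ok(x: float, y: float, ctype: str) -> bool:
        if layout.mode != "core_margin":
            return True
        bd = _border_distance(np.array(x), np.array(y), layout.image_size)
        if ctype in layout.margin_types:
            return bool(bd < layout.margin_band_width)
        if ctype in layout.core_types:
            return bool(bd >= layout.margin_band_width)
        return True

    for ctype in order:
        anchor = attract_b.get(ctype)
        anchors = None
        if anchor is not None:
            a_type, max_d = anchor
            anchors = np.asarray([c.centroid for c in cells if c.type == a_type])
            if anchors.size == 0:
                raise PlacementError(
                    f"attraction pair needs {a_type!r} cells placed before {ctype!r}")
        for _ in range(layout.n_cells.get(ctype, 0)):
            for attempt in range(max_attempts_per_cell):
                if anchors is None:
                    x = rng.uniform(pad, w - 1 - pad)
                    y = rng.uniform(pad, h - 1 - pad)
                else:
                    ax, ay = anchors[rng.integers(len(anchors))]
                    lo, hi = layout.min_center_distance, anchor[1]
                    r = math.sqrt(rng.uniform(lo ** 2, hi ** 2))
                    th = rng.uniform(0, 2 * math.pi)
                    x, y = ax + r * math.cos(th), ay + r * math.sin(th)
                    if not (pad <= x <= w - 1 - pad and pad <= y <= h - 1 - pad):
                        continue
                if _region_ok(x, y, ctype) and _ok(x, y):
                    cid = len(cells) + 1
                    cells.append(GroundTruth(
                        cell_id=cid, type=ctype, centroid=(x, y),
                        nucleus_radius=layout.nucleus_radius, mask_label=cid))
                    pts.append((x, y))
                    break
            else:
                raise PlacementError(
                    f"failed to place cell of type {ctype!r} after "
                    f"{max_attempts_per_cell} attempts: min_center_distance="
                    f"{layout.min_center_distance} µm is too dense for "
                    f"{sum(layout.n_cells.values())} cells in {layout.image_size}")
    return cells


# --------------------------------------------------------------------------- #
# rendering


def ground_truth_mask(cells: list[GroundTruth], image_size: tuple[int, int],
                      ring_width: float = 2.0) -> np.ndarray:
    """Rasterize cell footprints (nucleus disk + cytoplasm ring) to a label mask.

    Cells are painted in id order; where rings of neighboring cells overlap the
    later cell wins, so every label keeps at least its nucleus core.
    """
    h, w = image_size
    mask = np.zeros((h, w), dtype=np.int32)
    for c in cells:
        _paint_disk(mask, c.centroid, c.nucleus_radius + ring_width, c.mask_label)
    return mask


def _paint_disk(mask: np.ndarray, centroid: tuple[float, float],
                radius: float, label: int) -> None:
    h, w = mask.shape
    cx, cy = centroid
    x0, x1 = max(0, int(cx - radius) - 1), min(w, int(cx + radius) + 2)
    y0, y1 = max(0, int(cy - radius) - 1), min(h, int(cy + radius) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
    mask[y0:y1, x0:x1][inside] = label


def _nucleus_footprint(mask: np.ndarray, cell: GroundTruth) -> np.ndarray:
    h, w = mask.shape
    yy, xx = np.nonzero(mask == cell.mask_label)
    cx, cy = cell.centroid
    nuc = (xx - cx) ** 2 + (yy - cy) ** 2 <= cell.nucleus_radius ** 2
    return yy, xx, nuc


def render_roi(cells: list[GroundTruth], signatures: SignatureMatrix,
               noise: NoiseSpec, image_size: tuple[int, int],
               roi_id: str = "roi", ring_width: float = 2.0,
               dna_mean: float = 100.0, dna_sigma: float = 0.2,
               ) -> tuple[MultiplexImage, np.ndarray]:
    """Render cells to a multichannel image plus the ground-truth label mask.

    Channels are the signature markers in order, then the DNA channel. Marker
    intensity per cell is a single lognormal draw painted over the whole
    footprint; DNA is painted over the nucleus disk only. Background pixels
    carry ``background_mean``; optional Poisson resampling and isolated hot
    pixels are applied last.
    """
    unknown = {c.type for c in cells} - set(signatures.cell_types)
    if unknown:
        raise KeyError(f"cell types without signature: {sorted(unknown)}")
    if noise.hot_pixel_rate > 0 and noise.hot_pixel_amplitude <= 10 * max(
            signatures.mean.max(), dna_mean):
        raise ValueError("hot_pixel_amplitude must exceed 10 x any signature mean")

    h, w = image_size
    rng = np.random.default_rng(noise.seed)
    mask = ground_truth_mask(cells, image_size, ring_width)
    n_mark = len(signatures.markers)
    data = np.full((n_mark + 1, h, w), noise.background_mean, dtype=np.float64)

    for c in cells:
        t = signatures.row(c.type)
        yy, xx, nuc = _nucleus_footprint(mask, c)
        z = rng.standard_normal(n_mark + 1)
        vals = signatures.mean[t] * np.exp(signatures.dispersion[t] * z[:n_mark])
        for m in range(n_mark):
            data[m, yy, xx] = vals[m]
        data[n_mark, yy[nuc], xx[nuc]] = dna_mean * math.exp(dna_sigma * z[n_mark])

    if noise.poisson:
        data = rng.poisson(data).astype(np.float64)

    if noise.hot_pixel_rate > 0:
        for ch in range(n_mark + 1):
            idx = _isolated_hot_pixels(rng, (h, w), noise.hot_pixel_rate)
            data[ch].ravel()[idx] = noise.hot_pixel_amplitude

    image = MultiplexImage(roi_id=roi_id,
                           channels=list(signatures.markers) + [DNA_CHANNEL],
                           data=data.astype(np.float32))
    return image, mask


def _isolated_hot_pixels(rng: np.random.Generator, shape: tuple[int, int],
                         rate: float) -> np.ndarray:
    """Flat indices of hot pixels, pairwise Euclidean distance > 2 so that a
    radius-2 median disk never contains two of them."""
    h, w = shape
    n = rng.binomial(h * w, rate)
    idx = rng.choice(h * w, size=n, replace=False)
    ys, xs = idx // w, idx % w
    keep: list[int] = []
    ky: list[int] = []
    kx: list[int] = []
    for i in range(n):
        if keep:
            d2 = (np.asarray(ky) - ys[i]) ** 2 + (np.asarray(kx) - xs[i]) ** 2
            if d2.min() <= 4:
                continue
        keep.append(idx[i])
        ky.append(ys[i])
        kx.append(xs[i])
    return np.asarray(keep, dtype=np.int64)


def scribbles_from_ground_truth(cells: list[GroundTruth],
                                image_size: tuple[int, int],
                                ring_width: float = 2.0,
                                background_margin: float = 2.0,
                                max_per_class: int = 20_000) -> np.ndarray:
    """Sparse training labels from the ground truth, replacing interactive
    annotation: 1 = nuclei (eroded nucleus disks), 2 = cytoplasm (outer ring),
    3 = background (further than ``background_margin`` µm from any cell)."""
    from scipy import ndimage as ndi

    h, w = image_size
    lab = np.zeros((h, w), dtype=np.uint8)
    mask = ground_truth_mask(cells, image_size, ring_width)
    for c in cells:
        yy, xx = np.nonzero(mask == c.mask_label)
        cx, cy = c.centroid
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        r = c.nucleus_radius
        lab[yy[d2 <= (r - 2) ** 2], xx[d2 <= (r - 2) ** 2]] = 1
        ring = (d2 > (r + 0.5) ** 2) & (d2 <= (r + ring_width - 0.5) ** 2)
        lab[yy[ring], xx[ring]] = 2
    far = ndi.distance_transform_edt(mask == 0) > background_margin
    lab[far] = 3
    for cls in (1, 2, 3):
        yy, xx = np.nonzero(lab == cls)
        if len(yy) > max_per_class:
            sel = np.linspace(0, len(yy) - 1, max_per_class).astype(int)
            drop = np.ones(len(yy), dtype=bool)
            drop[sel] = False
            lab[yy[drop], xx[drop]] = 0
    return lab


# --------------------------------------------------------------------------- #
# cell-level sampling (no imaging), for clustering-scale experiments


def sample_cells(signatures: SignatureMatrix, n_per_type: dict[str, int],
                 seed: int, background: float = 0.5) -> pd.DataFrame:
    """Draw per-cell mean marker intensities directly from the signature model.

    Returns one row per cell with marker columns (dual counts) plus
    ``true_type``, bypassing image rendering for experiments at clustering
    scale (thousands of cells).
    """
    rng = np.random.default_rng(seed)
    frames = []
    for t, n in n_per_type.items():
        i = signatures.row(t)
        z = rng.standard_normal((n, len(signatures.markers)))
        vals = (signatures.mean[i] + background) * np.exp(signatures.dispersion[i] * z)
        df = pd.DataFrame(vals, columns=signatures.markers)
        df["true_type"] = t
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "cell_id", np.arange(1, len(out) + 1))
    return out


# --------------------------------------------------------------------------- #
# fixture I/O


def write_fixture(image: MultiplexImage, mask: np.ndarray,
                  cells: list[GroundTruth], panel: pd.DataFrame, out_dir) -> dict:
    """Write image/mask TIFFs plus ground-truth and panel CSVs; lossless."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / "image.tiff",
        "mask": out / "mask.tiff",
        "cells": out / "ground_truth.csv",
        "panel": out / "panel.csv",
    }
    write_image(image, paths["image"])
    write_mask(mask, paths["mask"])
    pd.DataFrame([{
        "cell_id": c.cell_id, "type": c.type, "x": c.centroid[0],
        "y": c.centroid[1], "nucleus_radius": c.nucleus_radius,
        "mask_label": c.mask_label,
    } for c in cells]).to_csv(paths["cells"], index=False)
    write_panel(panel, paths["panel"])
    return paths


def read_fixture(in_dir) -> tuple[MultiplexImage, np.ndarray, list[GroundTruth], pd.DataFrame]:
    d = Path(in_dir)
    image = read_image(d / "image.tiff")
    mask = read_mask(d / "mask.tiff")
    df = pd.read_csv(d / "ground_truth.csv")
    cells = [GroundTruth(cell_id=int(r.cell_id), type=str(r.type),
                         centroid=(float(r.x), float(r.y)),
                         nucleus_radius=float(r.nucleus_radius),
                         mask_label=int(r.mask_label))
             for r in df.itertuples()]
    panel = read_panel(d / "panel.csv")
    return image, mask, cells, panel


def synthetic_panel(signatures: SignatureMatrix,
                    segmentation: list[str] | None = None,
                    clustering: list[str] | None = None) -> pd.DataFrame:
    """Panel matching a signature matrix's marker set (DNA appended)."""
    if clustering is None:
        clustering = list(signatures.markers)
    if segmentation is None:
        expressed = {m for d in _SIGNATURE_DEFS.values() for m in d}
        segmentation = [m for m in ("CD45", "aSMA", "ZO-1") if m in signatures.markers
                        and m in expressed]
    return make_panel(list(signatures.markers), segmentation=segmentation,
                      clustering=clustering)
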