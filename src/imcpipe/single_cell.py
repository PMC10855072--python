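"""Single-cell quantification, quality control and intensity normalization.

The cell table has one row per segmented cell with metadata columns
(``cell_id``, ``roi_id``, ``x``, ``y``, ``area_um2``), raw per-marker mean
intensities in dual counts under the marker names, and — after
:func:`transform_normalize` — asinh/quantile-scaled values in ``<marker>_norm``
columns.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skimage.measure import regionprops_table

from .image import MultiplexImage

META_COLUMNS = ["cell_id", "roi_id", "x", "y", "area_um2"]

DEFAULT_MAX_AREA = 500.0     # µm²; larger objects are debris / merged cells
DEFAULT_HIGH_INTENSITY = 2.0  # dual counts; high in *all* markers = artifact
DEFAULT_LOW_INTENSITY = 0.01  # dual counts; low in *all* clustering markers


def marker_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns
            if c not in META_COLUMNS and not c.endswith("_norm")
            and c not in ("qc_pass", "qc_reason", "group", "cluster_id",
                          "phenotype", "immune_subtype", "true_type")]


def quantify(mask: np.ndarray, image: MultiplexImage) -> pd.DataFrame:
    """Mean marker intensity, area and centroid per cell.

    Area is pixel count × pixel_size² (1 µm²/px by default); the centroid is
    the mean pixel coordinate, reported as (x, y) in µm. Intensities should be
    hot-pixel-removed raw dual counts.
    """
    mask = np.asarray(mask)
    if mask.shape != image.shape:
        raise ValueError(f"mask {mask.shape} does not match image {image.shape}")
    if mask.max() == 0:
        return pd.DataFrame(columns=META_COLUMNS + list(image.channels))
    props = regionprops_table(
        mask, intensity_image=np.moveaxis(image.data, 0, -1),
        properties=("label", "area", "centroid", "intensity_mean"))
    px = image.pixel_size
    table = pd.DataFrame({
        "cell_id": props["label"],
        "roi_id": image.roi_id,
        "x": props["centroid-1"] * px,
        "y": props["centroid-0"] * px,
        "area_um2": props["area"] * px ** 2,
    })
    for i, name in enumerate(image.channels):
        table[name] = props[f"intensity_mean-{i}"]
    return table


def qc_filter(table: pd.DataFrame, clustering_markers: list[str],
              markers: list[str] | None = None,
              max_area: float = DEFAULT_MAX_AREA,
              high_intensity: float = DEFAULT_HIGH_INTENSITY,
              low_intensity: float = DEFAULT_LOW_INTENSITY,
              warn_fraction: float = 0.02) -> tuple[pd.DataFrame, dict]:
    """Drop likely debris and segmentation errors.

    A cell is excluded iff any of: (a) area > ``max_area`` µm²; (b) mean
    intensity > ``high_intensity`` in *every* marker simultaneously; (c) mean
    intensity < ``low_intensity`` in *every* clustering marker simultaneously.
    Returns the surviving cells (annotated with ``qc_pass``/``qc_reason``) and
    a report of per-rule counts; warns if more than ``warn_fraction`` of cells
    are discarded.
    """
    if not clustering_markers:
        raise ValueError("clustering_markers must be nonempty")
    if markers is None:
        markers = marker_columns(table)
    report = {"area": 0, "all_high": 0, "all_low": 0,
              "n_total": len(table), "n_discarded": 0, "fraction_discarded": 0.0}
    if table.empty:
        out = table.copy()
        out["qc_pass"] = pd.Series(dtype=bool)
        out["qc_reason"] = pd.Series(dtype=object)
        return out, report

    rule_area = table["area_um2"].to_numpy() > max_area
    rule_high = (table[markers].to_numpy() > high_intensity).all(axis=1)
    rule_low = (table[clustering_markers].to_numpy() < low_intensity).all(axis=1)
    excluded = rule_area | rule_high | rule_low

    reason = np.where(rule_area, "area",
                      np.where(rule_high, "all_high",
                               np.where(rule_low, "all_low", "")))
    report.update({
        "area": int(rule_area.sum()),
        "all_high": int(rule_high.sum()),
        "all_low": int(rule_low.sum()),
        "n_discarded": int(excluded.sum()),
        "fraction_discarded": float(excluded.mean()),
    })
    if report["fraction_discarded"] > warn_fraction:
        warnings.warn(
            f"QC discarded {report['fraction_discarded']:.1%} of cells "
            f"(> {warn_fraction:.0%}); check segmentation and thresholds")
    out = table.loc[~excluded].copy()
    out["qc_pass"] = True
    out["qc_reason"] = ""
    return out, report


def transform_normalize(table: pd.DataFrame, markers: list[str] | None = None,
                        cofactor: float = 1.0, lo: float = 0.01,
                        hi: float = 0.99) -> pd.DataFrame:
    """asinh-rescale then quantile-normalize marker intensities to [0, 1].

    Per marker, pooled over all cells in the table (all ROIs of a model are
    normalized jointly): y = asinh(x / cofactor); the ``lo`` and ``hi``
    quantiles of y map to 0 and 1 and values outside clip. A constant marker
    maps to all zeros. Results land in ``<marker>_norm`` columns.
    """
    if markers is None:
        markers = marker_columns(table)
    out = table.copy()
    for m in markers:
        y = np.arcsinh(out[m].to_numpy(dtype=float) / cofactor)
        if len(y) == 0:
            out[m + "_norm"] = y
            continue
        q_lo, q_hi = np.quantile(y, [lo, hi])
        if q_hi <= q_lo:
            out[m + "_norm"] = 0.0
        else:
            out[m + "_norm"] = np.clip((y - q_lo) / (q_hi - q_lo), 0.0, 1.0)
    return out
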