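"""Raw-channel cleanup and normalization.

Fixed pipeline order per channel: hot-pixel removal (local-median replacement
of bright outliers, disk radius 2, threshold 50 dual counts), scaling to the
99th percentile of the channel (never dividing by less than 10 dual counts,
clipped to [0, 1]), then an optional per-channel low-intensity threshold.
"""

from __future__ import annotations

import numpy as np

from .image import MultiplexImage
from .panel import role_markers

DEFAULT_HOT_PIXEL_RADIUS = 2
DEFAULT_HOT_PIXEL_THRESHOLD = 50.0
DEFAULT_P99_FLOOR = 10.0


def _disk_offsets(radius: int) -> list[tuple[int, int]]:
    r = int(radius)
    return [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)
            if dy * dy + dx * dx <= radius * radius]


def remove_hot_pixels(channel: np.ndarray,
                      radius: int = DEFAULT_HOT_PIXEL_RADIUS,
                      threshold: float = DEFAULT_HOT_PIXEL_THRESHOLD) -> np.ndarray:
    """Replace bright outliers by the local median.

    For each pixel, the median m over the Euclidean disk of given radius
    (clipped at image edges) is computed; pixels with value − m > threshold are
    set to m, all others are untouched. Only bright outliers are ever replaced,
    matching the nature of detector hot pixels.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("empty image")
    if radius < 1 or threshold <= 0:
        raise ValueError("radius must be >= 1 and threshold > 0")
    h, w = channel.shape
    stack = np.full((len(_disk_offsets(radius)), h, w), np.nan)
    for k, (dy, dx) in enumerate(_disk_offsets(radius)):
        ys = slice(max(0, dy), min(h, h + dy))
        xs = slice(max(0, dx), min(w, w + dx))
        ys_src = slice(max(0, -dy), min(h, h - dy))
        xs_src = slice(max(0, -dx), min(w, w - dx))
        stack[k, ys_src, xs_src] = channel[ys, xs]
    med = np.nanmedian(stack, axis=0)
    return np.where(channel - med > threshold, med, channel)


def normalize_p99(channel: np.ndarray, floor: float = DEFAULT_P99_FLOOR) -> np.ndarray:
    """Scale a channel by max(99th percentile, floor), saturating at 1.

    The percentile is taken over all pixels, zeros included; the floor keeps
    near-empty channels from being blown up by noise.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.min() < 0:
        raise ValueError("channel must be nonnegative")
    s = max(np.percentile(channel, 99), floor)
    return np.minimum(channel / s, 1.0)


def apply_low_threshold(channel: np.ndarray, low_threshold: float) -> np.ndarray:
    """Zero out values below the (visually tuned) per-channel threshold."""
    if low_threshold < 0:
        raise ValueError("low threshold must be >= 0")
    channel = np.asarray(channel, dtype=float)
    return np.where(channel < low_threshold, 0.0, channel)


def clean_channel(channel: np.ndarray, low_threshold: float = 0.0,
                  radius: int = DEFAULT_HOT_PIXEL_RADIUS,
                  threshold: float = DEFAULT_HOT_PIXEL_THRESHOLD,
                  floor: float = DEFAULT_P99_FLOOR) -> np.ndarray:
    out = remove_hot_pixels(channel, radius=radius, threshold=threshold)
    out = normalize_p99(out, floor=floor)
    return apply_low_threshold(out, low_threshold)


def build_stack(image: MultiplexImage, panel, role: str,
                low_thresholds: dict[str, float] | None = None,
                radius: int = DEFAULT_HOT_PIXEL_RADIUS,
                threshold: float = DEFAULT_HOT_PIXEL_THRESHOLD,
                floor: float = DEFAULT_P99_FLOOR) -> MultiplexImage:
    """Cleaned, normalized sub-stack of the channels flagged with ``role``
    (plus, for the segmentation role, the DNA channel), in panel order.

    ``low_thresholds`` maps marker name to its threshold on the [0, 1]
    normalized scale; unlisted markers default to 0.
    """
    markers = role_markers(panel, role)
    if role == "segmentation":
        markers = sorted(set(markers) | set(role_markers(panel, "dna")),
                         key=panel["target"].tolist().index)
    if not markers:
        raise ValueError(f"no markers flagged for role {role!r}")
    missing = [m for m in markers if m not in image.channels]
    if missing:
        raise KeyError(f"markers not present in image: {missing}")
    low = low_thresholds or {}
    data = np.stack([
        clean_channel(image.channel(m), low.get(m, 0.0),
                      radius=radius, threshold=threshold, floor=floor)
        for m in markers
    ])
    return MultiplexImage(roi_id=image.roi_id, channels=markers, data=data,
                          pixel_size=image.pixel_size)
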