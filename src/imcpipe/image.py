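"""In-memory containers and TIFF I/O for multichannel ROIs and label masks."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class MultiplexImage:
    """Channel stack of one ROI; 1 pixel = ``pixel_size``² µm² (default 1)."""

    roi_id: str
    channels: list[str]
    data: np.ndarray  # (C, H, W), nonnegative dual counts
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be (channels, H, W)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} planes"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.data)) or self.data.min() < 0:
            raise ValueError("intensities must be finite and nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not in image {self.roi_id!r}") from None

    def subset(self, names: list[str]) -> "MultiplexImage":
        return MultiplexImage(
            roi_id=self.roi_id,
            channels=list(names),
            data=np.stack([self.channel(n) for n in names]),
            pixel_size=self.pixel_size,
        )


def write_image(image: MultiplexImage, path) -> None:
    """Write a multichannel float32 TIFF; channel names go in the description."""
    meta = {"roi_id": image.roi_id, "channels": image.channels,
            "pixel_size": image.pixel_size}
    tifffile.imwrite(path, image.data.astype(np.float32),
                     description=json.dumps(meta))


def read_image(path) -> MultiplexImage:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    return MultiplexImage(roi_id=meta["roi_id"], channels=meta["channels"],
                          data=data, pixel_size=meta.get("pixel_size", 1.0))


def write_mask(mask: np.ndarray, path) -> None:
    mask = np.asarray(mask)
    if mask.min() < 0:
        raise ValueError("label mask must be nonnegative")
    tifffile.imwrite(path, mask.astype(np.uint32))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int64)
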