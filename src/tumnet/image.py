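"""Grayscale image container and PNG/JPEG round-tripping.

Intensities are kept as real numbers in [0, 255] internally so that
downstream arithmetic (fusion averaging, metrics) does not suffer double
rounding; quantization to 8-bit happens only on export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image


class ShapeMismatchError(ValueError):
    """Two images that must be co-registered have different dimensions."""


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale raster with intensities in [0, 255].

    Parameters
    ----------
    pixels
        2-D float array of intensities. Stored read-only.
    pixel_side_mm
        Optional physical side length of one pixel in millimetres.
    """

    pixels: np.ndarray
    pixel_side_mm: float | None = field(default=None)

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got ndim={arr.ndim}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("image must have positive height and width")
        if not np.isfinite(arr).all():
            raise ValueError("image contains non-finite intensities")
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError(
                f"intensities outside [0, 255]: min={arr.min()}, max={arr.max()}"
            )
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def to_uint8(self) -> np.ndarray:
        """Quantize to 8-bit: round half to even, clip to [0, 255]."""
        return np.clip(np.rint(self.pixels), 0, 255).astype(np.uint8)

    def require_same_shape(self, other: "GrayImage") -> None:
        if self.shape != other.shape:
            raise ShapeMismatchError(
                f"image shapes differ: {self.shape} vs {other.shape}"
            )


def read_image(path: str | Path, pixel_side_mm: float | None = None) -> GrayImage:
    """Read a PNG/JPEG file; color inputs are converted to luminance."""
    with Image.open(path) as im:
        gray = im.convert("L")
        arr = np.asarray(gray, dtype=np.float64)
    return GrayImage(arr, pixel_side_mm=pixel_side_mm)


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write as an 8-bit grayscale raster (format chosen by extension)."""
    Image.fromarray(img.to_uint8(), mode="L").save(path)
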