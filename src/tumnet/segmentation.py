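"""Threshold-and-shape tumor segmentation with physical area reporting.

The tumor region is recovered by simple intensity thresholding (Otsu by
default, or a fixed cutoff), 8-connected component labelling, and a
shape filter: a component counts as tumor only if its solidity exceeds
0.7 AND its pixel area exceeds 100 px (strict inequalities). Solidity —
component area divided by convex-hull area — separates compact tumor
blobs (solidity near 1) from elongated or ring-like structures such as
the skull. All passing components are kept, since residual tumor tissue
may be multifocal.

The physical area is ``total pixels * area_factor`` with the default
factor 0.264 mm^2 per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion as ndi_binary_erosion
from skimage import measure
from skimage.filters import threshold_otsu

from .image import GrayImage, ShapeMismatchError

#: Default shape-filter settings and pixel-to-mm^2 conversion.
DEFAULT_MIN_SOLIDITY = 0.7
DEFAULT_MIN_AREA_PX = 100
DEFAULT_AREA_FACTOR = 0.264


@dataclass(frozen=True)
class BinaryMask:
    """A boolean raster aligned with its source image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=bool)
        if arr.ndim != 2:
            raise ValueError("mask must be 2-D")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class ComponentStats:
    component_id: int
    area_px: int
    solidity: float
    centroid: tuple[float, float]
    bounding_box: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)


@dataclass(frozen=True)
class SegmentationResult:
    tumor_mask: BinaryMask
    components_kept: tuple[ComponentStats, ...]
    components_rejected: tuple[ComponentStats, ...]
    total_tumor_px: int
    tumor_area_mm2: float
    threshold: float


def binarize(
    img: GrayImage, method: str = "otsu", threshold: float | None = None
) -> tuple[BinaryMask, float]:
    """Binarize at an intensity cutoff; pixel is foreground iff intensity > t.

    ``method="otsu"`` derives t by Otsu's between-class-variance
    maximization on the 256-bin histogram; ``method="fixed"`` requires
    an explicit ``threshold`` in [0, 255]. Returns the mask and the
    threshold used.
    """
    if method == "otsu":
        pixels = img.pixels
        if np.ptp(pixels) == 0:
            # Degenerate constant image: nothing exceeds its own level.
            return BinaryMask(np.zeros(img.shape, dtype=bool)), float(pixels.flat[0])
        t = float(threshold_otsu(pixels, nbins=256))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed-threshold binarization requires a threshold")
        if not 0 <= threshold <= 255:
            raise ValueError(f"threshold must be in [0, 255], got {threshold}")
        t = float(threshold)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return BinaryMask(img.pixels > t), t


def extract_components(mask: BinaryMask) -> list[ComponentStats]:
    """8-connected components with area, solidity, centroid, and bbox."""
    labelled = measure.label(mask.pixels, connectivity=2)
    out = []
    for region in measure.regionprops(labelled):
        out.append(
            ComponentStats(
                component_id=int(region.label),
                area_px=int(region.area),
                solidity=float(region.solidity),
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                bounding_box=tuple(int(v) for v in region.bbox),
            )
        )
    return out


def filter_tumor(
    components: list[ComponentStats],
    min_solidity: float = DEFAULT_MIN_SOLIDITY,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
) -> tuple[list[ComponentStats], list[ComponentStats]]:
    """Split components into (kept, rejected) by the tumor shape rule.

    Kept requires solidity > min_solidity AND area > min_area_px, both
    strictly.
    """
    if min_solidity <= 0 or min_area_px <= 0:
        raise ValueError("filter thresholds must be positive")
    kept, rejected = [], []
    for c in components:
        (kept if c.solidity > min_solidity and c.area_px > min_area_px else rejected).append(c)
    return kept, rejected


def tumor_area_mm2(total_tumor_px: int, area_factor: float = DEFAULT_AREA_FACTOR) -> float:
    """Physical tumor area: pixel count times mm^2-per-pixel factor."""
    if total_tumor_px < 0:
        raise ValueError("pixel count cannot be negative")
    return total_tumor_px * area_factor


def segment(
    img: GrayImage,
    method: str = "otsu",
    threshold: float | None = None,
    min_solidity: float = DEFAULT_MIN_SOLIDITY,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    area_factor: float = DEFAULT_AREA_FACTOR,
) -> SegmentationResult:
    """Full segmentation: threshold -> components -> shape filter -> area."""
    mask, t = binarize(img, method=method, threshold=threshold)
    components = extract_components(mask)
    kept, rejected = filter_tumor(components, min_solidity, min_area_px)
    labelled = measure.label(mask.pixels, connectivity=2)
    keep_ids = {c.component_id for c in kept}
    tumor = np.isin(labelled, sorted(keep_ids)) if keep_ids else np.zeros_like(mask.pixels)
    total = int(tumor.sum())
    return SegmentationResult(
        tumor_mask=BinaryMask(tumor),
        components_kept=tuple(kept),
        components_rejected=tuple(rejected),
        total_tumor_px=total,
        tumor_area_mm2=tumor_area_mm2(total, area_factor),
        threshold=t,
    )


def tumor_outline(
    mask: BinaryMask, img: GrayImage, outline_value: float = 255.0
) -> GrayImage:
    """Mark the one-pixel-wide boundary of the mask on a copy of the image.

    The boundary is the mask minus its erosion; an empty mask returns
    the image unchanged.
    """
    if mask.shape != img.shape:
        raise ShapeMismatchError(
            f"mask shape {mask.shape} does not match image shape {img.shape}"
        )
    if mask.count == 0:
        return img
    eroded = ndi_binary_erosion(mask.pixels, structure=np.ones((3, 3), bool))
    boundary = mask.pixels & ~eroded
    out = img.pixels.copy()
    out[boundary] = outline_value
    return GrayImage(out, pixel_side_mm=img.pixel_side_mm)


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); two empty masks score 1."""
    pa = a.pixels if isinstance(a, BinaryMask) else np.asarray(a, bool)
    pb = b.pixels if isinstance(b, BinaryMask) else np.asarray(b, bool)
    if pa.shape != pb.shape:
        raise ShapeMismatchError(f"mask shapes differ: {pa.shape} vs {pb.shape}")
    total = int(pa.sum()) + int(pb.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((pa & pb).sum()) / total
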