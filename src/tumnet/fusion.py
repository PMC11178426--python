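"""Pixel-level fusion of co-registered MRI/CT slice pairs.

Pixel-level fusion combines two registered images by a per-pixel rule:
the fused intensity at (x, y) is the mean, maximum, or minimum of the two
source intensities at (x, y). Averaging carries a blend of both
modalities (soft tissue from MRI, bone from CT); max/min each favour the
brighter or darker modality pixelwise.

Fusion presumes the inputs are registered: images of different sizes are
rejected rather than silently resized, since a size mismatch almost
always indicates a registration fault upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .image import GrayImage

FUSION_METHODS = ("average", "maximum", "minimum")

#: Side length expected by the Tumnet classifier.
MODEL_INPUT_SIDE = 227


@dataclass(frozen=True)
class FusionResult:
    """Outcome of fusing two registered grayscale images."""

    fused: GrayImage
    method: str
    source_shapes: tuple[tuple[int, int], tuple[int, int]]


def _fuse(a: GrayImage, b: GrayImage, method: str) -> FusionResult:
    a.require_same_shape(b)
    if method == "average":
        pixels = (a.pixels + b.pixels) / 2.0
    elif method == "maximum":
        pixels = np.maximum(a.pixels, b.pixels)
    elif method == "minimum":
        pixels = np.minimum(a.pixels, b.pixels)
    else:
        raise ValueError(f"unknown fusion method {method!r}; use one of {FUSION_METHODS}")
    mm = a.pixel_side_mm if a.pixel_side_mm is not None else b.pixel_side_mm
    return FusionResult(
        fused=GrayImage(pixels, pixel_side_mm=mm),
        method=method,
        source_shapes=(a.shape, b.shape),
    )


def fuse_average(a: GrayImage, b: GrayImage) -> FusionResult:
    """Fused pixel = (a + b) / 2, kept real-valued internally."""
    return _fuse(a, b, "average")


def fuse_max(a: GrayImage, b: GrayImage) -> FusionResult:
    """Fused pixel = elementwise maximum of the two sources."""
    return _fuse(a, b, "maximum")


def fuse_min(a: GrayImage, b: GrayImage) -> FusionResult:
    """Fused pixel = elementwise minimum of the two sources."""
    return _fuse(a, b, "minimum")


def fuse(a: GrayImage, b: GrayImage, method: str) -> FusionResult:
    """Dispatch on ``method`` in {"average", "maximum", "minimum"}.

    "max"/"min" are accepted as aliases.
    """
    aliases = {"max": "maximum", "min": "minimum", "avg": "average", "mean": "average"}
    return _fuse(a, b, aliases.get(method, method))


def resize_for_model(
    img: GrayImage,
    target: tuple[int, int] = (MODEL_INPUT_SIDE, MODEL_INPUT_SIDE),
) -> GrayImage:
    """Resize to the classifier's input size (bilinear, clamped to [0, 255]).

    An image already at the target size is returned unchanged, bit for bit.
    Typical use is shrinking 256x256 atlas slices to 227x227.
    """
    th, tw = target
    if th < 1 or tw < 1:
        raise ValueError(f"target dimensions must be positive, got {target}")
    if img.shape == (th, tw):
        return img
    out = _sk_resize(
        img.pixels, (th, tw), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return GrayImage(np.clip(out, 0, 255), pixel_side_mm=None)
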