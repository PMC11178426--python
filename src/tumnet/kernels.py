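"""Classic 3x3 convolution kernels and direct 2-D convolution.

These are the hand-designed filters traditionally used to illustrate
what a convolution layer extracts: smoothing, edges, and oriented
lines. ``apply_kernel`` performs true convolution (the kernel is
flipped, as in g(x,y) = sum_k sum_l W(k,l) f(x-k, y-l)) with zero
padding and "same" output size.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .image import GrayImage

#: Named 3x3 filter presets.
KERNELS: dict[str, np.ndarray] = {
    "low_pass": np.full((3, 3), 1.0 / 9.0),
    "high_pass": np.array(
        [[-1, -1, -1],
         [-1,  8, -1],
         [-1, -1, -1]], dtype=float),
    "line_detection": np.array(
        [[-1, -1, -1],
         [ 2,  2,  2],
         [-1, -1, -1]], dtype=float),
    "vertical_line_detection": np.array(
        [[-1, 2, -1],
         [-1, 2, -1],
         [-1, 2, -1]], dtype=float),
    "slant_45": np.array(
        [[-1, -1,  2],
         [-1,  2, -1],
         [ 2, -1, -1]], dtype=float),
    "slant_minus_45": np.array(
        [[ 2, -1, -1],
         [-1,  2, -1],
         [-1, -1,  2]], dtype=float),
}


def apply_kernel(img: GrayImage | np.ndarray, kernel: np.ndarray | str) -> np.ndarray:
    """Convolve a 2-D image with a 3x3 kernel (zero padding, same size).

    ``kernel`` may be a preset name from :data:`KERNELS` or any 3x3
    array. Returns the raw filtered values (which may leave [0, 255],
    e.g. for zero-sum edge kernels).
    """
    if isinstance(kernel, str):
        try:
            kernel = KERNELS[kernel]
        except KeyError:
            raise KeyError(
                f"unknown kernel preset {kernel!r}; available: {sorted(KERNELS)}"
            ) from None
    kernel = np.asarray(kernel, dtype=float)
    if kernel.shape != (3, 3):
        raise ValueError(f"kernel must be 3x3, got {kernel.shape}")
    pixels = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=float)
    # scipy's convolve flips the kernel, i.e. true convolution
    return ndimage.convolve(pixels, kernel, mode="constant", cval=0.0)
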