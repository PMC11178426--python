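"""Image-quality and classification metrics for fusion and segmentation.

Covers the full evaluation suite: structural similarity (SSIM) between
a source modality and the fused image ("SSIM tissue" against the MRI,
"SSIM bone" against the CT), Shannon entropy of the intensity
histogram, first-order statistics, and confusion-matrix rates
(sensitivity, specificity, accuracy) for pixel- or slice-level
decisions.

SSIM here is the standard windowed form

    SSIM(x, y) = (2 mu_x mu_y + C1)(2 sigma_xy + C2)
                 / ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2))

averaged over sliding windows, with C1 = (k1 L)^2, C2 = (k2 L)^2,
k1 = 0.01, k2 = 0.03, and L the dynamic range (255 for 8-bit images).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter

from .image import GrayImage, ShapeMismatchError
from .segmentation import BinaryMask


class UndefinedMetricError(ArithmeticError):
    """A rate whose denominator is zero (e.g. sensitivity with no positives)."""


@dataclass(frozen=True)
class SSIMParams:
    """Stabilizing constants and dynamic range for SSIM."""

    k1: float = 0.01
    k2: float = 0.03
    L: float = 255.0
    window: int = 7
    windowed: bool = True

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0 or self.L <= 0:
            raise ValueError("k1, k2, and L must all be positive")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be a positive odd size")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel (or case) counts of a binary decision versus truth."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def _pixels(img: GrayImage | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=float)


def ssim(
    ref: GrayImage | np.ndarray,
    test: GrayImage | np.ndarray,
    params: SSIMParams = SSIMParams(),
) -> float:
    """Structural similarity between two equally sized grayscale images.

    Windowed mean of the local luminance-contrast-structure product
    (uniform window, population moments); ``params.windowed=False``
    computes a single global window instead. Identical images score
    exactly 1; the value always lies in [-1, 1].
    """
    x = _pixels(ref).astype(np.float64)
    y = _pixels(test).astype(np.float64)
    if x.shape != y.shape:
        raise ShapeMismatchError(f"image shapes differ: {x.shape} vs {y.shape}")
    c1 = (params.k1 * params.L) ** 2
    c2 = (params.k2 * params.L) ** 2
    if params.windowed:
        w = min(params.window, *x.shape)
        mean = lambda a: uniform_filter(a, size=w, mode="reflect")
    else:
        w = 1
        mean = lambda a: np.full_like(a, a.mean())
    mx, my = mean(x), mean(y)
    vx = mean(x * x) - mx * mx
    vy = mean(y * y) - my * my
    cxy = mean(x * y) - mx * my
    num = (2 * mx * my + c1) * (2 * cxy + c2)
    den = (mx * mx + my * my + c1) * (vx + vy + c2)
    ssim_map = num / den
    pad = w // 2  # average over fully valid windows only
    if pad and min(ssim_map.shape) > 2 * pad:
        ssim_map = ssim_map[pad:-pad, pad:-pad]
    return float(np.mean(ssim_map))


def entropy(img: GrayImage | np.ndarray, levels: int = 256) -> float:
    """Shannon entropy of the intensity histogram, in bits.

    -sum p(k) log2 p(k) over ``levels`` equal-width bins spanning
    [0, 255] (bin k collects intensities rounding to level k). Constant
    images give 0; a uniform 256-level histogram gives 8 bits.
    """
    pixels = _pixels(img)
    if pixels.size == 0:
        raise ValueError("cannot compute entropy of an empty image")
    counts = np.bincount(
        np.clip(np.rint(pixels), 0, levels - 1).astype(np.int64).ravel(),
        minlength=levels,
    )
    p = counts[counts > 0] / pixels.size
    return float(-(p * np.log2(p)).sum() + 0.0)  # +0.0 avoids returning -0.0


def confusion(pred: BinaryMask | np.ndarray, truth: BinaryMask | np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts; TP+FP+TN+FN equals the pixel total."""
    p = pred.pixels if isinstance(pred, BinaryMask) else np.asarray(pred, bool)
    t = truth.pixels if isinstance(truth, BinaryMask) else np.asarray(truth, bool)
    if p.shape != t.shape:
        raise ShapeMismatchError(f"mask shapes differ: {p.shape} vs {t.shape}")
    return ConfusionCounts(
        TP=int((p & t).sum()),
        FP=int((p & ~t).sum()),
        TN=int((~p & ~t).sum()),
        FN=int((~p & t).sum()),
    )


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN) — the fraction of true disease found."""
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive truth")
    return c.TP / (c.TP + c.FN)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP) — the fraction of true background kept clean."""
    if c.TN + c.FP == 0:
        raise UndefinedMetricError("specificity undefined: no negative truth")
    return c.TN / (c.TN + c.FP)


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total."""
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined: zero total")
    return (c.TP + c.TN) / c.total


def first_order_stats(
    img: GrayImage | np.ndarray, normalized: bool = False
) -> tuple[float, float, float]:
    """(mean, std, variance) of the intensities, population convention.

    With ``normalized=True`` intensities are scaled by 1/255 to [0, 1]
    first, matching reporting on a normalized scale.
    """
    pixels = _pixels(img)
    if pixels.size == 0:
        raise ValueError("cannot compute statistics of an empty image")
    if normalized:
        pixels = pixels / 255.0
    return float(pixels.mean()), float(pixels.std()), float(pixels.var())


@dataclass(frozen=True)
class MetricsReport:
    """Assembled metric suite for one fusion/segmentation run.

    Confusion-derived fields are None when no truth mask was supplied;
    ``ssim_bone`` is None in single-modality runs.
    """

    ssim_tissue: Optional[float]
    ssim_bone: Optional[float]
    entropy_bits: float
    mean: float
    std: float
    variance: float
    tumor_entropy_bits: Optional[float] = None
    tumor_mean: Optional[float] = None
    tumor_std: Optional[float] = None
    tumor_variance: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    accuracy: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def fusion_report(
    mri: Optional[GrayImage],
    ct: Optional[GrayImage],
    fused: GrayImage,
    tumor_mask: Optional[BinaryMask] = None,
    truth_mask: Optional[BinaryMask] = None,
    ssim_params: SSIMParams = SSIMParams(),
    normalized_stats: bool = True,
) -> MetricsReport:
    """Assemble all metrics for a fused (or single-modality) image.

    SSIM tissue compares the MRI input with the fused image; SSIM bone
    compares the CT input. First-order statistics and entropy are
    reported for the fused image and, when a tumor mask is given, for
    the tumor region alone. Confusion rates are included only when a
    ground-truth mask is supplied.
    """
    mean, std, var = first_order_stats(fused, normalized=normalized_stats)
    report = {
        "ssim_tissue": ssim(mri, fused, ssim_params) if mri is not None else None,
        "ssim_bone": ssim(ct, fused, ssim_params) if ct is not None else None,
        "entropy_bits": entropy(fused),
        "mean": mean, "std": std, "variance": var,
    }
    if tumor_mask is not None and tumor_mask.count > 0:
        region = fused.pixels[tumor_mask.pixels]
        tmean, tstd, tvar = first_order_stats(region, normalized=normalized_stats)
        report.update(
            tumor_entropy_bits=entropy(region),
            tumor_mean=tmean, tumor_std=tstd, tumor_variance=tvar,
        )
    if truth_mask is not None:
        if tumor_mask is None:
            raise ValueError("confusion metrics need a predicted tumor mask")
        c = confusion(tumor_mask, truth_mask)
        report.update(
            sensitivity=sensitivity(c) if c.TP + c.FN > 0 else None,
            specificity=specificity(c) if c.TN + c.FP > 0 else None,
            accuracy=accuracy(c),
        )
    return MetricsReport(**report)
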