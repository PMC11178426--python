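"""Synthetic registered MRI-like / CT-like brain phantoms.

Each phantom pair shares one anatomy: an elliptical brain, a thin
elliptical skull ring, and optionally a compact bright tumor blob that
appears in both modalities at the same location (the pair is registered
by construction). The MRI-like slice carries the soft-tissue signal —
smooth mid-gray tissue texture with only a faint skull — while the
CT-like slice shows a bright skull ring over nearly flat, dark tissue.
Intensities are chosen so that on the average-fused image the tumor and
skull sit well above the tissue mode: a global Otsu threshold then
captures skull + tumor, and the solidity/area filter removes the
ring-shaped skull, leaving the tumor.

These phantoms emulate registered atlas slice pairs for testing; they
are not anatomically realistic and model no MR sequence or CT physics.
Optional distractors (small bright blobs, a low-solidity cross) support
negative tests of the shape filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .fusion import fuse
from .image import GrayImage
from .segmentation import BinaryMask

SIDE = 227

#: Anatomy defaults (row/col semi-axes in pixels).
BRAIN_CENTER = (113.0, 113.0)
BRAIN_SEMI_AXES = (88.0, 72.0)
SKULL_INNER_SCALE = 1.03
SKULL_OUTER_SCALE = 1.11

#: Modality contrast defaults on the 8-bit scale.
MRI_TISSUE = 45.0
MRI_TEXTURE_AMP = 12.0
MRI_SKULL = 65.0
CT_TISSUE = 15.0
CT_TEXTURE_AMP = 4.0
CT_SKULL = 240.0


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for one registered phantom pair."""

    image_size: tuple[int, int] = (SIDE, SIDE)
    tumor_present: bool = True
    tumor_center: tuple[float, float] = (140.0, 95.0)
    tumor_axes: tuple[float, float] = (14.0, 11.0)  # semi-axes (rows, cols)
    tumor_angle: float = 0.0  # degrees
    tumor_intensity: float = 230.0
    tissue_contrast: float = MRI_TISSUE
    bone_contrast: float = CT_SKULL
    noise_sigma: float = 5.0
    salt_pepper_fraction: float = 0.0
    n_small_distractors: int = 0
    small_distractor_radius: float = 4.0
    low_solidity_distractor: bool = False
    rng_seed: int = 0


@dataclass(frozen=True)
class PhantomSample:
    """One generated pair with its ground truth."""

    mri_like: GrayImage
    ct_like: GrayImage
    truth_mask: BinaryMask
    label: str  # "tumor" | "no_tumor"
    spec: PhantomSpec

    def fused(self, method: str = "average") -> GrayImage:
        """Pixel-level fusion of the pair (average by default)."""
        return fuse(self.mri_like, self.ct_like, method).fused


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    angle_deg: float = 0.0,
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dr, dc = rr - center[0], cc - center[1]
    th = np.deg2rad(angle_deg)
    u = dr * np.cos(th) + dc * np.sin(th)
    v = -dr * np.sin(th) + dc * np.cos(th)
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _smooth_texture(
    shape: tuple[int, int], amp: float, rng: np.random.Generator, sigma: float = 6.0
) -> np.ndarray:
    noise = gaussian_filter(rng.standard_normal(shape), sigma)
    sd = noise.std()
    return amp * noise / sd if sd > 0 else noise


def _cross_mask(shape, center, arm: int = 20, width: int = 3) -> np.ndarray:
    mask = np.zeros(shape, bool)
    r, c = int(center[0]), int(center[1])
    h = width // 2
    mask[r - h : r + h + 1, c - arm : c + arm + 1] = True
    mask[r - arm : r + arm + 1, c - h : c + h + 1] = True
    return mask


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one registered MRI-like / CT-like pair from a spec.

    Deterministic for a fixed ``spec.rng_seed``. Raises if the tumor
    ellipse is not fully inside the brain tissue region.
    """
    shape = spec.image_size
    rng = np.random.default_rng(spec.rng_seed)

    brain = _ellipse_mask(shape, BRAIN_CENTER, BRAIN_SEMI_AXES)
    skull_outer = _ellipse_mask(
        shape, BRAIN_CENTER,
        (BRAIN_SEMI_AXES[0] * SKULL_OUTER_SCALE, BRAIN_SEMI_AXES[1] * SKULL_OUTER_SCALE),
    )
    skull_inner = _ellipse_mask(
        shape, BRAIN_CENTER,
        (BRAIN_SEMI_AXES[0] * SKULL_INNER_SCALE, BRAIN_SEMI_AXES[1] * SKULL_INNER_SCALE),
    )
    skull = skull_outer & ~skull_inner

    if spec.tumor_present:
        tumor = _ellipse_mask(shape, spec.tumor_center, spec.tumor_axes, spec.tumor_angle)
        if not tumor.any():
            raise ValueError("tumor ellipse rasterized to zero pixels")
        if (tumor & ~brain).any():
            raise ValueError("tumor ellipse extends outside the brain region")
    else:
        tumor = np.zeros(shape, bool)

    bright = tumor.copy()
    if spec.n_small_distractors:
        offsets = [(-45.0, 40.0), (20.0, 55.0), (-20.0, -50.0), (45.0, 25.0)]
        for i in range(spec.n_small_distractors):
            dr, dc = offsets[i % len(offsets)]
            blob = _ellipse_mask(
                shape, (BRAIN_CENTER[0] + dr, BRAIN_CENTER[1] + dc),
                (spec.small_distractor_radius, spec.small_distractor_radius),
            )
            bright |= blob & brain
    if spec.low_solidity_distractor:
        bright |= _cross_mask(shape, (75.0, 140.0)) & brain

    # smoothed bright-structure layer: high interior value, soft 1-px rim
    bright_layer = gaussian_filter(bright.astype(float), 1.0)

    def _compose(tissue_level, texture_amp, skull_level):
        img = np.zeros(shape)
        img[brain] = tissue_level
        img += _smooth_texture(shape, texture_amp, rng) * brain
        img[skull] = skull_level
        img = np.maximum(img, bright_layer * spec.tumor_intensity)
        return img

    mri = _compose(spec.tissue_contrast, MRI_TEXTURE_AMP, MRI_SKULL)
    ct = _compose(CT_TISSUE, CT_TEXTURE_AMP, spec.bone_contrast)

    for img in (mri, ct):
        if spec.noise_sigma > 0:
            img += rng.normal(0.0, spec.noise_sigma, shape)
        if spec.salt_pepper_fraction > 0:
            flip = rng.random(shape) < spec.salt_pepper_fraction
            img[flip] = np.where(rng.random(shape)[flip] < 0.5, 0.0, 255.0)

    mri_img = GrayImage(np.clip(mri, 0, 255))
    ct_img = GrayImage(np.clip(ct, 0, 255))
    return PhantomSample(
        mri_like=mri_img,
        ct_like=ct_img,
        truth_mask=BinaryMask(tumor),
        label="tumor" if spec.tumor_present else "no_tumor",
        spec=spec,
    )


def generate_dataset(
    n: int,
    tumor_fraction: float = 0.5,
    base_spec: PhantomSpec | None = None,
    rng_seed: int = 0,
) -> list[PhantomSample]:
    """Generate ``n`` phantoms, floor(n * tumor_fraction) of them positive.

    Tumor geometry (center, semi-axes, orientation, intensity) is
    randomized per positive sample within ranges that keep the blob
    compact, brighter than tissue, and inside the brain; every sample
    gets fresh tissue texture and noise. Reproducible from ``rng_seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= tumor_fraction <= 1:
        raise ValueError("tumor_fraction must be in [0, 1]")
    base = base_spec if base_spec is not None else PhantomSpec()
    master = np.random.default_rng(rng_seed)
    n_pos = int(np.floor(n * tumor_fraction))
    samples = []
    for i in range(n):
        seed = int(master.integers(2**31))
        sub = np.random.default_rng(seed)
        present = i < n_pos
        if present:
            # sample a center/orientation, then shrink toward the brain
            # center until the ellipse fits inside the tissue region
            a = float(sub.uniform(10.0, 16.0))
            b = float(sub.uniform(8.0, 13.0))
            angle = float(sub.uniform(0.0, 180.0))
            dr = float(sub.uniform(-45.0, 45.0))
            dc = float(sub.uniform(-35.0, 35.0))
            ext = max(a, b) + 1.0  # conservative reach of the rotated ellipse
            while (
                ((abs(dr) + ext) / (BRAIN_SEMI_AXES[0] - 1)) ** 2
                + ((abs(dc) + ext) / (BRAIN_SEMI_AXES[1] - 1)) ** 2
                > 1.0
            ):
                dr *= 0.85
                dc *= 0.85
            r, c = BRAIN_CENTER[0] + dr, BRAIN_CENTER[1] + dc
            spec = replace(
                base,
                tumor_present=True,
                tumor_center=(r, c),
                tumor_axes=(a, b),
                tumor_angle=angle,
                tumor_intensity=float(sub.uniform(215.0, 245.0)),
                rng_seed=seed,
            )
        else:
            spec = replace(base, tumor_present=False, rng_seed=seed)
        samples.append(generate_phantom(spec))
    order = master.permutation(n)
    return [samples[i] for i in order]
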