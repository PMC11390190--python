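"""Ultrasound preprocessing: SRAD despeckling, histogram equalization,
annotation removal, and geometric augmentation.

SRAD (speckle-reduction anisotropic diffusion) is an edge-preserving PDE
filter driven by the instantaneous coefficient of variation (ICOV): the
diffusion coefficient approaches 1 in homogeneous speckle (ICOV near the
speckle scale q0) and collapses to 0 at edges (ICOV far above q0), so
speckle is smoothed while boundaries survive.  The speckle scale decays
exponentially with diffusion time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform


@dataclass(frozen=True)
class SradParams:
    """SRAD settings.

    time_step must respect the explicit-scheme stability bound (<= 0.25);
    q0 is the initial speckle-scale coefficient, decayed per iteration as
    ``q0 * exp(-rho * t)``.
    """

    n_iterations: int = 30
    time_step: float = 0.05
    q0: float = 1.0
    rho: float = 0.05

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0 < self.time_step <= 0.25):
            raise ValueError("time_step must be in (0, 0.25]")
        if not (0 < self.q0 <= 1.0):
            raise ValueError("q0 must be in (0, 1]")


def srad_filter(image: np.ndarray, params: SradParams = SradParams()) -> np.ndarray:
    """Despeckle with speckle-reduction anisotropic diffusion.

    Explicit 4-neighbour scheme with symmetric (edge-replicating) borders.
    Returns a float64 image clipped to the input range; a constant image
    is a fixed point.
    """
    f = np.asarray(image, dtype=np.float64)
    if not np.isfinite(f).all():
        raise ValueError("input contains non-finite pixels")
    lo, hi = f.min(), f.max()
    I = f + 1e-6  # strictly positive for the ratio statistics

    for it in range(params.n_iterations):
        q0t = params.q0 * np.exp(-params.rho * it * params.time_step)
        q0sq = q0t * q0t

        # one-sided differences (replicated borders)
        iN = np.roll(I, 1, axis=0); iN[0, :] = I[0, :]
        iS = np.roll(I, -1, axis=0); iS[-1, :] = I[-1, :]
        iW = np.roll(I, 1, axis=1); iW[:, 0] = I[:, 0]
        iE = np.roll(I, -1, axis=1); iE[:, -1] = I[:, -1]

        dN = iN - I
        dS = iS - I
        dW = iW - I
        dE = iE - I

        g2 = (dN ** 2 + dS ** 2 + dW ** 2 + dE ** 2) / (I * I)
        lap = (dN + dS + dW + dE) / I

        num = 0.5 * g2 - 0.0625 * lap * lap
        den = (1.0 + 0.25 * lap) ** 2
        q2 = np.clip(num / np.maximum(den, 1e-12), 0, None)

        c = 1.0 / (1.0 + (q2 - q0sq) / (q0sq * (1.0 + q0sq)))
        c = np.clip(c, 0.0, 1.0)

        # divergence with the conduction coefficient on the staggered grid
        cS = np.roll(c, -1, axis=0); cS[-1, :] = c[-1, :]
        cE = np.roll(c, -1, axis=1); cE[:, -1] = c[:, -1]
        div = cS * dS + c * dN + cE * dE + c * dW
        I = I + (params.time_step / 4.0) * div

    return np.clip(I - 1e-6, lo, hi)


def histogram_equalize(image: np.ndarray) -> np.ndarray:
    """Classical 8-bit histogram equalization.

    Maps level v to ``round(255 * (cdf(v) - cdf_min) / (N - cdf_min))``
    where cdf is the cumulative histogram of the input; the monotone map
    preserves the rank order of distinct levels.  A constant image is
    returned unchanged.
    """
    img = np.asarray(image)
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    nonzero = cdf[hist > 0]
    cdf_min = nonzero[0]
    n = img.size
    if n == cdf_min:  # single gray level
        return img.copy()
    lut = np.round(255.0 * (cdf - cdf_min) / (n - cdf_min)).astype(np.uint8)
    return lut[img]


def remove_annotations(image: np.ndarray,
                       intensity_threshold: int = 240,
                       tophat_threshold: int = 40) -> np.ndarray:
    """Remove bright thin physician marks by morphological inpainting.

    A pixel is treated as a mark when it is both bright (>= the intensity
    threshold) and thin — a strong white top-hat response under a 3x3
    cross, i.e. it vanishes under a small opening.  The detected mask is
    dilated by one pixel and those pixels are replaced with the grayscale
    opening of the image (the local tissue level with thin bright
    structures suppressed); everything else is untouched.
    """
    img = np.asarray(image)
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    opened = ndimage.grey_opening(img, footprint=cross)
    tophat = img.astype(np.int16) - opened.astype(np.int16)
    mark = (img >= intensity_threshold) & (tophat >= tophat_threshold)
    if not mark.any():
        return img.copy()
    mark = ndimage.binary_dilation(mark, structure=np.ones((3, 3), dtype=bool))
    # inpaint with an opening large enough to cover the dilated mark width
    fill = ndimage.grey_opening(img, footprint=np.ones((5, 5), dtype=bool))
    out = img.copy()
    out[mark] = fill[mark]
    return out


@dataclass(frozen=True)
class AugmentPlan:
    """Spatial-geometric augmentation settings.

    ``multiplier`` is the total number of output images per input — the
    resized original plus ``multiplier - 1`` randomized variants.  The
    default multiplier of 10 enlarges each image with nine transformed
    companions; larger factors mostly add redundancy.
    """

    multiplier: int = 10
    crop_size: int = 230
    allow_flip: bool = True
    allow_rotation: bool = True
    allow_scale: bool = True
    rotation_range: float = 15.0      # degrees, +/-
    scale_range: tuple[float, float] = (0.9, 1.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")
        if self.crop_size < 1:
            raise ValueError("crop_size must be >= 1")


def _random_crop(img: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    h, w = img.shape
    top = int(rng.integers(0, h - size + 1))
    left = int(rng.integers(0, w - size + 1))
    return img[top:top + size, left:left + size]


def augment(image: np.ndarray, plan: AugmentPlan) -> list[np.ndarray]:
    """Expand one image into ``plan.multiplier`` crop_size x crop_size images.

    The first output is the original resized to crop_size; the rest apply
    (seeded) random rotation/scale affine warps, horizontal/vertical
    flips and a random crop.  Warped-in border pixels are filled by
    interpolation with reflected content so the frame stays full.
    """
    img = np.asarray(image)
    h, w = img.shape
    if plan.crop_size > min(h, w):
        raise ValueError("crop_size larger than image")
    rng = np.random.default_rng(plan.seed)

    out: list[np.ndarray] = []
    base = sktransform.resize(img, (plan.crop_size, plan.crop_size),
                              preserve_range=True, anti_aliasing=True)
    out.append(np.clip(np.round(base), 0, 255).astype(np.uint8))

    for _ in range(plan.multiplier - 1):
        var = img
        if plan.allow_rotation or plan.allow_scale:
            angle = (np.deg2rad(rng.uniform(-plan.rotation_range, plan.rotation_range))
                     if plan.allow_rotation else 0.0)
            scale = (rng.uniform(*plan.scale_range) if plan.allow_scale else 1.0)
            if angle != 0.0 or scale != 1.0:
                center = np.array([w, h]) / 2.0
                tf = (sktransform.AffineTransform(translation=-center)
                      + sktransform.AffineTransform(rotation=angle, scale=scale)
                      + sktransform.AffineTransform(translation=center))
                var = sktransform.warp(var.astype(np.float64), tf.inverse,
                                       mode="reflect", preserve_range=True)
        if plan.allow_flip:
            if rng.random() < 0.5:
                var = var[:, ::-1]
            if rng.random() < 0.5:
                var = var[::-1, :]
        var = _random_crop(np.ascontiguousarray(var), plan.crop_size, rng)
        out.append(np.clip(np.round(var), 0, 255).astype(np.uint8))
    return out
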