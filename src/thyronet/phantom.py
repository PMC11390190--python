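"""Synthetic B-mode ultrasound phantoms with ground-truth nodule masks.

Real B-mode images of thyroid tissue are dominated by fully developed
speckle — multiplicative, roughly Gamma-distributed intensity noise on an
otherwise smooth echo level — with nodules appearing as hypoechoic
(darker) roughly elliptical regions.  The generator here reproduces those
two features plus the bright caliper marks sonographers burn into the
image, so every downstream stage (despeckling, enhancement, segmentation,
detection, evaluation) can be exercised against known ground truth.

Speckle model: ``pixel = background_mean * G`` with ``G ~ Gamma(shape,
1/shape)`` (unit mean), the standard surrogate for fully developed
speckle after envelope detection.  The coefficient of variation of the
background is therefore ``1/sqrt(shape)``.  Nodules are rotated ellipses
whose interior echo level is scaled by ``(1 - nodule_contrast)``, with a
2-px Gaussian-smoothed rim so the transition is not a hard edge.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage


class PlacementError(RuntimeError):
    """Raised when non-overlapping nodule placement fails after bounded retries."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom image."""

    height: int = 512
    width: int = 512
    n_nodules: int = 1
    nodule_radius_range: tuple[float, float] = (20.0, 60.0)
    nodule_contrast: float = 0.5
    speckle_shape: float = 6.0
    background_mean: float = 140.0
    annotation_marks: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ValueError("phantom must be at least 64x64")
        if self.n_nodules < 0:
            raise ValueError("n_nodules must be >= 0")
        lo, hi = self.nodule_radius_range
        if not (0 < lo <= hi):
            raise ValueError("invalid nodule_radius_range")
        if hi >= min(self.height, self.width) / 2:
            raise ValueError("max nodule radius must be < min(height,width)/2")
        if not (0.0 < self.nodule_contrast <= 1.0):
            raise ValueError("nodule_contrast must be in (0,1]")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")
        if not (0.0 < self.background_mean <= 255.0):
            raise ValueError("background_mean must be in (0,255]")


@dataclass
class PhantomSample:
    """A generated phantom: 8-bit image, binary mask and nodule geometry."""

    image: np.ndarray          # uint8 (H, W)
    mask: np.ndarray           # uint8 (H, W), 0 background / 255 nodule
    nodules: list[tuple[tuple[float, float], tuple[float, float], float]]
    spec: PhantomSpec

    @property
    def label(self) -> int:
        return int(len(self.nodules) > 0)


def _nodule_interior(shape: tuple[int, int],
                     center: tuple[float, float],
                     axes: tuple[float, float],
                     rotation: float) -> np.ndarray:
    """Boolean mask of a rotated ellipse interior."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    dr = rr - center[0]
    dc = cc - center[1]
    ct, st = np.cos(rotation), np.sin(rotation)
    u = ct * dc + st * dr
    v = -st * dc + ct * dr
    return (u / axes[1]) ** 2 + (v / axes[0]) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate one seeded phantom.

    The echo-level field starts flat at ``background_mean``, nodule
    interiors are attenuated by ``1 - nodule_contrast`` (rim smoothed
    with a 2-px Gaussian), multiplicative unit-mean Gamma speckle is
    applied, and the result is clipped to [0, 255] and quantized to 8
    bits.  Identical specs give bit-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    lo, hi = spec.nodule_radius_range

    nodules = []
    hard_mask = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_nodules):
        placed = False
        for _attempt in range(200):
            a = rng.uniform(lo, hi)
            b = rng.uniform(lo, hi)
            rot = rng.uniform(0, np.pi)
            rmax = max(a, b)
            cy = rng.uniform(rmax + 2, h - rmax - 2)
            cx = rng.uniform(rmax + 2, w - rmax - 2)
            interior = _nodule_interior((h, w), (cy, cx), (a, b), rot)
            if not (interior & hard_mask).any():
                hard_mask |= interior
                nodules.append(((cy, cx), (a, b), rot))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place {spec.n_nodules} non-overlapping nodules "
                f"of radius {spec.nodule_radius_range} in {h}x{w}")

    # Smooth attenuation field: 1 inside background, (1-contrast) inside nodules,
    # with a ~2 px Gaussian transition at the rim.
    atten = np.ones((h, w), dtype=np.float64)
    atten[hard_mask] = 1.0 - spec.nodule_contrast
    atten = ndimage.gaussian_filter(atten, sigma=2.0)

    echo = spec.background_mean * atten
    speckle = rng.gamma(shape=spec.speckle_shape,
                        scale=1.0 / spec.speckle_shape, size=(h, w))
    image = np.clip(echo * speckle, 0, 255).astype(np.uint8)

    if spec.annotation_marks:
        image = add_annotation_marks(image, seed=spec.seed + 1)

    mask = np.where(hard_mask, 255, 0).astype(np.uint8)
    return PhantomSample(image=image, mask=mask, nodules=nodules, spec=spec)


def add_annotation_marks(image: np.ndarray, seed: int) -> np.ndarray:
    """Superimpose bright caliper crosses and dashed segments.

    Emulates the measurement marks physicians burn into clinical frames;
    the preprocessing stage is expected to remove them.  Returns a new
    array; the input is untouched.  All mark pixels have value >= 240.
    """
    rng = np.random.default_rng(seed)
    out = image.copy()
    h, w = out.shape
    n_marks = int(rng.integers(2, 7))
    for _ in range(n_marks):
        cy = int(rng.integers(10, h - 10))
        cx = int(rng.integers(10, w - 10))
        val = int(rng.integers(240, 256))
        if rng.random() < 0.6:
            # caliper cross: 7-px arms, 1 px wide
            arm = 3
            out[cy - arm:cy + arm + 1, cx] = val
            out[cy, cx - arm:cx + arm + 1] = val
        else:
            # short dashed segment (horizontal or vertical)
            length = int(rng.integers(8, 16))
            if rng.random() < 0.5:
                xs = np.arange(cx, min(cx + length, w))
                out[cy, xs[::2]] = val
            else:
                ys = np.arange(cy, min(cy + length, h))
                out[ys[::2], cx] = val
    return out


def generate_dataset(spec: PhantomSpec, n: int, seed: int,
                     out_dir: str | Path,
                     nodule_prob: float = 1.0) -> Path:
    """Write ``n`` phantoms (image + mask PNGs) and a CSV manifest.

    Each sample ``i`` is generated from ``spec`` re-seeded with a stream
    derived from ``(seed, i)``, so the dataset is order-independent and
    re-running with identical arguments reproduces byte-identical files.
    ``nodule_prob`` draws, per sample, whether the phantom carries
    ``spec.n_nodules`` nodules or none — giving a labeled mixed dataset.
    Returns the manifest path.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        # counter-based per-sample stream: stable under dataset reordering
        sample_seed = int(hashlib.sha256(f"{seed}:{i}".encode()).hexdigest()[:8], 16)
        has_nodule = (np.random.default_rng(sample_seed ^ 0x5EED).random()
                      < nodule_prob)
        s = replace(spec, seed=sample_seed,
                    n_nodules=spec.n_nodules if has_nodule else 0)
        sample = generate_phantom(s)
        img_path = out_dir / f"phantom_{i:04d}.png"
        mask_path = out_dir / f"phantom_{i:04d}_mask.png"
        iio.imwrite(img_path, sample.image)
        iio.imwrite(mask_path, sample.mask)
        rows.append((img_path.name, mask_path.name, sample.label))
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_path", "mask_path", "label"])
        writer.writerows(rows)
    return manifest
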