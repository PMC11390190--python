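"""The segmentation-then-classification cascade.

The segmentation network turns each 353x353 image patch into a 44x44
probability map (8 input pixels per map cell).  The map is binarized,
cleaned by erosion then dilation, and split into 8-connected candidate
regions.  A 64x64 classifier patch is attached to a candidate region
when it is centered in the region and covers at least 80% of the
region's area; patches attached to correctly segmented nodule regions
become positive training samples, everything else negative.  At
inference the classifier re-scores each candidate region and the
detections are ranked by score.

Coordinates are 0-based, row-major, with half-open patch extents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage


@dataclass
class ProbabilityMap:
    """Per-cell nodule probabilities for one source patch."""

    grid: np.ndarray                       # (h, w) floats in [0, 1]
    origin: tuple[int, int] = (0, 0)       # patch top-left in the full image
    scale: int = 8                         # input pixels per map cell

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=np.float64)
        if g.min() < 0 or g.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        self.grid = g


@dataclass
class CandidateRegion:
    """An 8-connected component of the segmented probability map."""

    pixel_set: np.ndarray                  # (n, 2) array of (row, col) cells
    mean_probability: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixel_set, dtype=np.int64).reshape(-1, 2)
        if px.shape[0] == 0:
            raise ValueError("pixel_set must be nonempty")
        self.pixel_set = px

    @property
    def area(self) -> int:
        return int(self.pixel_set.shape[0])

    @property
    def centroid(self) -> tuple[float, float]:
        return (float(self.pixel_set[:, 0].mean()),
                float(self.pixel_set[:, 1].mean()))

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(min_row, min_col, max_row_exclusive, max_col_exclusive)."""
        return (int(self.pixel_set[:, 0].min()), int(self.pixel_set[:, 1].min()),
                int(self.pixel_set[:, 0].max()) + 1, int(self.pixel_set[:, 1].max()) + 1)

    def contains(self, point: tuple[float, float]) -> bool:
        r, c = int(round(point[0])), int(round(point[1]))
        return bool(((self.pixel_set[:, 0] == r) & (self.pixel_set[:, 1] == c)).any())


@dataclass
class PatchSample:
    """A sampled patch with its full-image placement and (optional) label."""

    patch: np.ndarray                      # (C, s, s) or (s, s)
    center: tuple[int, int]                # full-image (row, col)
    label: str = "unlabeled"               # positive | negative | unlabeled
    source_region: CandidateRegion | None = None

    @property
    def size(self) -> int:
        return int(self.patch.shape[-1])


def _extract(image: np.ndarray, top: int, left: int, size: int) -> np.ndarray:
    if image.ndim == 2:
        return image[top:top + size, left:left + size]
    return image[:, top:top + size, left:left + size]


def sample_patches(image: np.ndarray, size: int, n: int, seed: int,
                   mask: np.ndarray | None = None,
                   positive_fraction: float = 0.0) -> list[PatchSample]:
    """Uniformly sample ``n`` patches of ``size`` x ``size`` (seeded).

    If a ground-truth mask is given, a ``positive_fraction`` of the
    draws center on mask-positive pixels (oversampling lesion patches
    for training); the rest are uniform over valid placements.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    h, w = image.shape[-2:]
    if size > min(h, w):
        raise ValueError("patch larger than image")
    rng = np.random.default_rng(seed)
    half = size // 2
    pos_coords = None
    if mask is not None and positive_fraction > 0:
        rr, cc = np.nonzero(mask)
        keep = ((rr >= half) & (rr < h - (size - half))
                & (cc >= half) & (cc < w - (size - half)))
        if keep.any():
            pos_coords = np.stack([rr[keep], cc[keep]], axis=1)
    out: list[PatchSample] = []
    for _ in range(n):
        if pos_coords is not None and rng.random() < positive_fraction:
            cy, cx = pos_coords[rng.integers(len(pos_coords))]
            top, left = int(cy) - half, int(cx) - half
        else:
            top = int(rng.integers(0, h - size + 1))
            left = int(rng.integers(0, w - size + 1))
        patch = _extract(image, top, left, size)
        out.append(PatchSample(patch=np.ascontiguousarray(patch),
                               center=(top + half, left + half)))
    return out


def segment_map(pmap: ProbabilityMap, threshold: float = 0.5,
                erode_se: np.ndarray | None = None,
                dilate_se: np.ndarray | None = None) -> list[CandidateRegion]:
    """Binarize -> erode -> dilate -> 8-connected components.

    Erosion removes blobs smaller than the element (isolated map noise);
    the following dilation restores the interiors of surviving regions.
    Regions are returned largest-first, ties broken by row-major
    centroid order.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    if erode_se is None:
        erode_se = np.ones((3, 3), dtype=bool)
    if dilate_se is None:
        dilate_se = np.ones((3, 3), dtype=bool)
    binary = pmap.grid >= threshold
    cleaned = ndimage.binary_erosion(binary, structure=erode_se)
    cleaned = ndimage.binary_dilation(cleaned, structure=dilate_se)
    labels, n = ndimage.label(cleaned, structure=np.ones((3, 3), dtype=bool))
    regions = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        mean_p = float(pmap.grid[coords[:, 0], coords[:, 1]].mean())
        regions.append(CandidateRegion(pixel_set=coords, mean_probability=mean_p))
    regions.sort(key=lambda r: (-r.area, r.centroid[0], r.centroid[1]))
    return regions


def upscale_region(region: CandidateRegion, scale: int = 8,
                   origin: tuple[int, int] = (0, 0)) -> CandidateRegion:
    """Expand each map cell to a scale x scale block in full-image pixels."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    cells = region.pixel_set
    dr, dc = np.meshgrid(np.arange(scale), np.arange(scale), indexing="ij")
    offs = np.stack([dr.ravel(), dc.ravel()], axis=1)          # (scale^2, 2)
    base = cells * scale + np.asarray(origin)
    pixels = (base[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    return CandidateRegion(pixel_set=pixels,
                           mean_probability=region.mean_probability)


def downscale_region(region: CandidateRegion, scale: int = 8,
                     origin: tuple[int, int] = (0, 0)) -> CandidateRegion:
    """Inverse of :func:`upscale_region` for block-aligned regions."""
    cells = np.unique((region.pixel_set - np.asarray(origin)) // scale, axis=0)
    return CandidateRegion(pixel_set=cells,
                           mean_probability=region.mean_probability)


def _patch_region_coverage(patch: PatchSample, region: CandidateRegion) -> float:
    """Fraction of the region's pixels inside the patch extent."""
    half = patch.size // 2
    top = patch.center[0] - half
    left = patch.center[1] - half
    px = region.pixel_set
    inside = ((px[:, 0] >= top) & (px[:, 0] < top + patch.size)
              & (px[:, 1] >= left) & (px[:, 1] < left + patch.size))
    return float(inside.sum()) / region.area


def region_gt_overlap(region: CandidateRegion, gt_mask: np.ndarray) -> float:
    """Fraction of the region's pixels lying on ground-truth nodule."""
    px = region.pixel_set
    h, w = gt_mask.shape
    valid = (px[:, 0] >= 0) & (px[:, 0] < h) & (px[:, 1] >= 0) & (px[:, 1] < w)
    if not valid.any():
        return 0.0
    hits = gt_mask[px[valid, 0], px[valid, 1]] > 0
    return float(hits.sum()) / region.area


def label_patches(patches: Sequence[PatchSample],
                  regions: Sequence[CandidateRegion],
                  gt_mask: np.ndarray,
                  area_fraction: float = 0.8,
                  correct_overlap: float = 0.5) -> list[PatchSample]:
    """Auto-label classifier patches from segmentation candidates.

    A patch attaches to a region when its center lies in the region and
    the patch covers at least ``area_fraction`` (default 80%) of the
    region's pixel area.  Attached patches are positive iff the region
    is correctly segmented — at least ``correct_overlap`` of its area on
    ground truth; everything else (including unattached patches) is
    negative.  Patches and regions must share the full-image frame.
    """
    if not (0.0 < area_fraction <= 1.0):
        raise ValueError("area_fraction must be in (0, 1]")
    out = []
    for p in patches:
        attached = None
        for region in regions:
            if region.contains(p.center) and \
                    _patch_region_coverage(p, region) >= area_fraction:
                attached = region
                break
        if attached is None:
            label = "negative"
        else:
            correct = region_gt_overlap(attached, gt_mask) >= correct_overlap
            label = "positive" if correct else "negative"
        out.append(PatchSample(patch=p.patch, center=p.center,
                               label=label, source_region=attached))
    return out


# --- multiview (test-time symmetry averaging) -------------------------------

_VIEWS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda a: a,
    "hflip": lambda a: a[..., :, ::-1],
    "vflip": lambda a: a[..., ::-1, :],
    "rot180": lambda a: a[..., ::-1, ::-1],
}

DEFAULT_VIEWS = ("identity", "hflip", "vflip", "rot180")


def multiview_predict(network, patch: np.ndarray,
                      views: Sequence[str] = DEFAULT_VIEWS) -> ProbabilityMap:
    """Average the network's map over symmetry-transformed inputs.

    Each view's output map is mapped back through the inverse transform
    (every default view is its own inverse) before averaging.
    """
    if not views:
        raise ValueError("views must be nonempty")
    for v in views:
        if v not in _VIEWS:
            raise ValueError(f"unknown view {v!r}")
    x = np.asarray(patch, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    acc = None
    for v in views:
        t = _VIEWS[v]
        out = np.asarray(network.predict(np.ascontiguousarray(t(x))[None]))
        out = np.squeeze(out)
        out = t(out)  # axis-aligned symmetries are involutions
        acc = out.astype(np.float64) if acc is None else acc + out
    grid = np.clip(acc / len(views), 0.0, 1.0)
    scale = x.shape[-1] // grid.shape[-1]
    return ProbabilityMap(grid=grid, scale=max(scale, 1))


@dataclass(frozen=True)
class DetectConfig:
    """End-to-end detection settings."""

    patch_size: int = 353
    stride: int = 176                 # ~50% tile overlap
    map_scale: int = 8
    threshold: float = 0.5
    views: tuple[str, ...] = DEFAULT_VIEWS
    classifier_patch: int = 64
    n_classifier_patches: int = 1
    seed: int = 0


def _two_channel(image: np.ndarray, enhanced: np.ndarray | None) -> np.ndarray:
    """Pair the preprocessed image with its enhanced companion (channel 1);
    falls back to duplicating channel 0."""
    ch0 = np.asarray(image, dtype=np.float32)
    ch1 = ch0 if enhanced is None else np.asarray(enhanced, dtype=np.float32)
    return np.stack([ch0, ch1], axis=0)


def stitch_probability_maps(maps: Sequence[ProbabilityMap],
                            image_shape: tuple[int, int],
                            scale: int = 8) -> ProbabilityMap:
    """Average overlapping patch maps onto one full-image map grid."""
    gh = -(-image_shape[0] // scale)
    gw = -(-image_shape[1] // scale)
    acc = np.zeros((gh, gw))
    cnt = np.zeros((gh, gw))
    for m in maps:
        r0 = m.origin[0] // scale
        c0 = m.origin[1] // scale
        h, w = m.grid.shape
        acc[r0:r0 + h, c0:c0 + w] += m.grid
        cnt[r0:r0 + h, c0:c0 + w] += 1.0
    grid = np.divide(acc, cnt, out=np.zeros_like(acc), where=cnt > 0)
    return ProbabilityMap(grid=grid, origin=(0, 0), scale=scale)


def detect(image: np.ndarray, cnn15, cnn4,
           config: DetectConfig = DetectConfig(),
           enhanced: np.ndarray | None = None) -> list[tuple[CandidateRegion, float]]:
    """Full cascade on one image: tile -> multiview segmentation maps ->
    stitch -> segment -> classifier re-scoring.

    Returns ``(region, score)`` pairs, regions in full-image pixel
    coordinates, sorted by descending score.  ``cnn15`` and ``cnn4`` may
    be any objects exposing ``predict``; the image is reflect-padded so
    the tiling covers the frame.
    """
    img2 = _two_channel(image, enhanced)
    _, h, w = img2.shape
    ps, stride = config.patch_size, config.stride
    if h < ps or w < ps:
        pad_h, pad_w = max(ps - h, 0), max(ps - w, 0)
        img2 = np.pad(img2, ((0, 0), (0, pad_h), (0, pad_w)), mode="reflect")
        _, h, w = img2.shape

    tops = list(range(0, h - ps + 1, stride))
    lefts = list(range(0, w - ps + 1, stride))
    if tops[-1] != h - ps:
        tops.append(h - ps)
    if lefts[-1] != w - ps:
        lefts.append(w - ps)

    maps = []
    for top in tops:
        for left in lefts:
            patch = img2[:, top:top + ps, left:left + ps]
            m = multiview_predict(cnn15, patch, views=config.views)
            maps.append(ProbabilityMap(grid=m.grid, origin=(top, left),
                                       scale=config.map_scale))
    full = stitch_probability_maps(maps, (h, w), scale=config.map_scale)
    regions = segment_map(full, threshold=config.threshold)

    cps = config.classifier_patch
    detections = []
    for i, region in enumerate(regions):
        up = upscale_region(region, scale=config.map_scale)
        cy, cx = up.centroid
        half = cps // 2
        top = int(np.clip(round(cy) - half, 0, h - cps))
        left = int(np.clip(round(cx) - half, 0, w - cps))
        patch = img2[:, top:top + cps, left:left + cps]
        probs = np.asarray(cnn4.predict(patch[None]))
        score = float(probs.reshape(-1)[-1]) if probs.size > 1 else float(probs)
        detections.append((up, score))
    detections.sort(key=lambda t: -t[1])
    return detections
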