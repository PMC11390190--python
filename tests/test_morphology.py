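"""Soft-morphology operators against exhaustive rank-order oracles, the
classical-limit equivalence suite, and the additive enhancement rules."""

import numpy as np
import pytest
from scipy import ndimage

from thyronet.morphology import (EnhanceParams, StructuringSystem, cross_mask,
                                 default_systems, enhance,
                                 extract_feature_stack, soft_dilate,
                                 soft_erode, soft_open, white_tophat_layer)


def rank_oracle(img, ss, smallest):
    """Per-pixel sorted-multiset extraction with edge-replicated borders."""
    h, w = img.shape
    ph, pw = ss.B.shape[0] // 2, ss.B.shape[1] // 2
    padded = np.pad(img, ((ph, ph), (pw, pw)), mode="edge")
    out = np.empty_like(img, dtype=np.float64)
    for i in range(h):
        for j in range(w):
            window = padded[i:i + ss.B.shape[0], j:j + ss.B.shape[1]]
            multiset = []
            for a, b in np.argwhere(ss.A):
                multiset.extend([window[a, b]] * ss.k)
            for a, b in np.argwhere(ss.B & ~ss.A):
                multiset.append(window[a, b])
            multiset.sort()
            out[i, j] = multiset[ss.k - 1] if smallest else multiset[-ss.k]
    return out


@pytest.fixture(params=[(3, 1, False), (3, 2, False), (5, 2, False),
                        (3, 2, True), (5, 3, True)],
                ids=lambda p: f"size{p[0]}-k{p[1]}-{'soft' if p[2]else 'cross'}")
def system(request):
    size, k, soft_boundary = request.param
    return StructuringSystem.cross(size, k=k, soft_boundary=soft_boundary)


class TestSoftOperators:
    def test_erode_matches_exhaustive_oracle(self, rng, system):
        img = rng.uniform(0, 255, size=(9, 9))
        assert np.allclose(soft_erode(img, system), rank_oracle(img, system, True))

    def test_dilate_matches_exhaustive_oracle(self, rng, system):
        img = rng.uniform(0, 255, size=(7, 7))
        assert np.allclose(soft_dilate(img, system), rank_oracle(img, system, False))

    def test_duality(self, rng, system):
        img = rng.uniform(-50, 50, size=(8, 8))
        assert np.allclose(soft_dilate(-img, system), -soft_erode(img, system))

    def test_constant_image_invariant(self, system):
        img = np.full((6, 6), 42.0)
        for op in (soft_erode, soft_dilate, soft_open):
            assert np.allclose(op(img, system), img)

    def test_invalid_systems_rejected(self):
        with pytest.raises(ValueError):
            StructuringSystem.cross(3, k=0)
        with pytest.raises(ValueError):  # core not a subset of support
            StructuringSystem(B=cross_mask(3), A=np.ones((3, 3), dtype=bool), k=1)


class TestClassicalLimit:
    """k=1, A=B reduces every soft operator to classical grayscale
    morphology (checked against the independent scipy implementation)."""

    @pytest.fixture
    def classical(self):
        return StructuringSystem(B=cross_mask(3), A=cross_mask(3), k=1)

    def test_erosion_dilation_match_scipy(self, rng, classical):
        img = rng.uniform(0, 255, size=(12, 12))
        foot = classical.B
        assert np.allclose(soft_erode(img, classical),
                           ndimage.grey_erosion(img, footprint=foot, mode="nearest"))
        assert np.allclose(soft_dilate(img, classical),
                           ndimage.grey_dilation(img, footprint=foot, mode="nearest"))

    def test_opening_matches_scipy_and_removes_peak(self, rng, classical):
        img = rng.uniform(0, 100, size=(10, 10))
        assert np.allclose(soft_open(img, classical),
                           ndimage.grey_opening(img, footprint=classical.B,
                                                mode="nearest"))
        flat = np.zeros((9, 9))
        flat[4, 4] = 100.0
        assert np.allclose(soft_open(flat, classical), 0.0)

    def test_opening_idempotent(self, rng, classical):
        img = rng.uniform(0, 255, size=(10, 10))
        once = soft_open(img, classical)
        assert np.allclose(soft_open(once, classical), once)


class TestWhiteTophat:
    def test_flat_image_zero_layer(self, system):
        assert np.allclose(white_tophat_layer(np.full((8, 8), 9.0), system), 0.0)

    def test_isolated_peak_recovered(self):
        ss = StructuringSystem.cross(3, k=1)
        img = np.zeros((9, 9))
        img[4, 4] = 100.0
        layer = white_tophat_layer(img, ss)
        assert layer[4, 4] == 100.0
        assert np.count_nonzero(layer) == 1

    def test_layer_equals_image_minus_opening_oracle(self, rng, system):
        img = rng.uniform(0, 255, size=(8, 8))
        opened = rank_oracle(rank_oracle(img, system, True),
                             system.reflected(), False)
        assert np.allclose(white_tophat_layer(img, system),
                           np.maximum(img - opened, 0.0))


class TestFeatureStack:
    def test_three_default_layers_and_flat_zero(self):
        img = np.full((16, 16), 50.0)
        for cascaded in (True, False):
            stack = extract_feature_stack(img, default_systems(), cascaded=cascaded)
            assert len(stack.layers) == 3
            assert all(np.allclose(l, 0.0) for l in stack.layers)

    def test_granulometry_separates_scales(self):
        # 1-px peak -> layer 1 only; 5-px plateau -> only layers >= 2
        img = np.zeros((24, 24))
        img[4, 4] = 80.0
        img[12:17, 12:17] = 60.0
        systems = default_systems(k=1)
        stack = extract_feature_stack(img, systems, cascaded=True)
        assert stack.layers[0][4, 4] == 80.0
        assert stack.layers[1][4, 4] == 0.0 and stack.layers[2][4, 4] == 0.0
        # plateau interior untouched at the smallest scale (the 3-px cross
        # fits); its bulk is extracted only at the larger scales
        assert stack.layers[0][13:16, 13:16].max() == 0.0
        plateau = np.zeros_like(img, dtype=bool)
        plateau[12:17, 12:17] = True
        assert (stack.layers[1][plateau].max() > 0
                or stack.layers[2][plateau].max() > 0)

    def test_cascade_telescopes(self, rng):
        # anti-extensive case (k=1): image - g_n == sum of layers exactly
        img = rng.uniform(0, 255, size=(20, 20))
        stack = extract_feature_stack(img, default_systems(k=1), cascaded=True)
        assert np.allclose(img - stack.opened_final, sum(stack.layers))

    def test_unordered_systems_rejected(self, rng):
        img = rng.uniform(0, 255, size=(8, 8))
        bad = [StructuringSystem.cross(5), StructuringSystem.cross(3)]
        with pytest.raises(ValueError):
            extract_feature_stack(img, bad)


class TestEnhance:
    def test_flat_image_unchanged(self):
        img = np.full((16, 16), 90, dtype=np.uint8)
        assert np.array_equal(enhance(img), img)

    def test_subthreshold_pixels_bit_identical(self, nodule_phantom):
        img = nodule_phantom.image
        params = EnhanceParams(m_fraction=2 / 3)
        out = enhance(img, params=params)
        m = params.m_fraction * float(img.max())
        below = img < m
        assert np.array_equal(out[below], img[below])

    def test_pointwise_monotone_nondecreasing(self, nodule_phantom):
        out = enhance(nodule_phantom.image)
        assert (out.astype(int) >= nodule_phantom.image.astype(int)).all()

    def test_peak_boost_matches_oracle(self, rng):
        # single bright peak, k=1 systems, weights 1: boosted value is
        # min(255, f + sum of oracle top-hat layers)
        img = np.zeros((9, 9), dtype=np.uint8)
        img[4, 4] = 200
        systems = default_systems(k=1)
        f = img.astype(np.float64)
        layers = []
        g = f
        for ss in systems:
            opened = rank_oracle(rank_oracle(g, ss, True), ss.reflected(), False)
            layers.append(np.maximum(g - opened, 0.0))
            g = opened
        expected = min(255.0, f[4, 4] + sum(l[4, 4] for l in layers))
        out = enhance(img, systems)
        assert out[4, 4] == expected

    def test_empty_systems_rejected(self, nodule_phantom):
        with pytest.raises(ValueError):
            enhance(nodule_phantom.image, [])
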