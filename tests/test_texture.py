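import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardioquant import (
    MultichannelImage,
    haralick_descriptors,
    masked_glcm,
    nuclear_texture,
    wga_thickness,
)
from cardioquant.errors import ContractError, DegenerateInputError, InsufficientTextureError
from cardioquant.segmentation import LabelMap
from cardioquant.texture import DEFAULT_OFFSETS, quantize


def brute_force_glcm(intensity, mask, n_levels, offsets):
    """Independent pair-enumeration oracle for the masked GLCM."""
    q = quantize(np.asarray(intensity, float), np.asarray(mask, bool), n_levels)
    counts = np.zeros((n_levels, n_levels))
    n_pairs = 0
    nrow, ncol = mask.shape
    for r in range(nrow):
        for c in range(ncol):
            if not mask[r, c]:
                continue
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nrow and 0 <= c2 < ncol and mask[r2, c2]:
                    counts[q[r, c], q[r2, c2]] += 1
                    n_pairs += 1
    counts = counts + counts.T
    return counts / counts.sum(), n_pairs


class TestMaskedGLCM:
    def test_constant_patch_single_cell(self):
        intensity = np.ones((2, 2))
        glcm = masked_glcm(intensity, np.ones((2, 2), bool))
        assert (glcm.matrix > 0).sum() == 1
        assert glcm.matrix.sum() == pytest.approx(1.0)
        assert glcm.matrix[0, 0] == pytest.approx(1.0)

    def test_checkerboard_extreme_levels(self):
        intensity = np.indices((4, 4)).sum(axis=0) % 2 * 1.0
        glcm = masked_glcm(intensity, np.ones((4, 4), bool), n_levels=8, offsets=((0, 1),))
        nz = np.argwhere(glcm.matrix > 0)
        assert set(map(tuple, nz)) == {(0, 7), (7, 0)}

    def test_background_never_pollutes(self):
        intensity = np.zeros((6, 6))
        intensity[2:4, 2:4] = 0.5
        mask = np.zeros((6, 6), bool)
        mask[2:4, 2:4] = True
        glcm = masked_glcm(intensity, mask)
        # all in-mask pixels equal -> one cell despite 0.0 background all around
        assert (glcm.matrix > 0).sum() == 1

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_oracle_equivalence_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        intensity = rng.random((16, 16))
        mask = rng.random((16, 16)) < 0.6
        if mask.sum() < 8:
            mask[4:8, 4:8] = True
        glcm = masked_glcm(intensity, mask)
        oracle, n_pairs = brute_force_glcm(intensity, mask, 8, DEFAULT_OFFSETS)
        np.testing.assert_array_equal(glcm.matrix, oracle)
        assert glcm.n_pairs == n_pairs

    def test_symmetry_exact(self):
        rng = np.random.default_rng(3)
        glcm = masked_glcm(rng.random((20, 20)), np.ones((20, 20), bool))
        np.testing.assert_array_equal(glcm.matrix, glcm.matrix.T)

    def test_single_pixel_mask_rejected(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        with pytest.raises(InsufficientTextureError):
            masked_glcm(np.ones((5, 5)), mask)

    def test_empty_mask_rejected(self):
        with pytest.raises(InsufficientTextureError):
            masked_glcm(np.ones((5, 5)), np.zeros((5, 5), bool))


class TestHaralick:
    def test_constant_region_descriptors(self):
        glcm = masked_glcm(np.ones((4, 4)), np.ones((4, 4), bool))
        d = haralick_descriptors(glcm)
        assert d.contrast == 0
        assert d.energy == 1
        assert d.homogeneity == 1
        assert d.entropy == 0
        assert d.correlation is None  # undefined, sentinel not a number

    def test_checkerboard_hand_computed(self):
        intensity = np.indices((4, 4)).sum(axis=0) % 2 * 1.0
        glcm = masked_glcm(intensity, np.ones((4, 4), bool), n_levels=8, offsets=((0, 1),))
        d = haralick_descriptors(glcm)
        assert d.contrast == pytest.approx(49.0)  # (8-1)^2
        assert d.homogeneity == pytest.approx(1 / 8)
        assert d.correlation == pytest.approx(-1.0)

    def test_antidiagonal_pair_hand_computed(self):
        p = np.zeros((3, 3))
        p[0, 1] = p[1, 0] = 0.5
        d = haralick_descriptors(p)
        assert d.entropy == pytest.approx(1.0)  # 1 bit
        assert d.energy == pytest.approx(0.5)
        assert d.correlation == pytest.approx(-1.0)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ContractError):
            haralick_descriptors(np.ones((4, 4)))

    def test_descriptor_ranges(self):
        rng = np.random.default_rng(8)
        glcm = masked_glcm(rng.random((30, 30)), np.ones((30, 30), bool))
        d = haralick_descriptors(glcm)
        assert 0 <= d.homogeneity <= 1
        assert 0 < d.energy <= 1
        assert d.entropy >= 0 and d.contrast >= 0


class TestImageLevelTexture:
    def _img_labels(self, amplitude, seed=5):
        from scipy import ndimage as ndi

        rng = np.random.default_rng(seed)
        speckle = ndi.gaussian_filter(rng.standard_normal((64, 64)), 1.5)
        speckle /= speckle.std()
        raster = np.clip(0.5 + amplitude * speckle, 0, 1)
        mask = np.zeros((64, 64), bool)
        mask[16:48, 16:48] = True
        labels = LabelMap(labels=mask.astype(int), n_objects=1, source_role="nuclear")
        return MultichannelImage(nuclear=np.where(mask, raster, 0.05)), labels

    def test_contrast_monotone_in_speckle_amplitude(self):
        img_lo, labels = self._img_labels(0.05)
        img_hi, _ = self._img_labels(0.25)
        lo = nuclear_texture(img_lo, labels)
        hi = nuclear_texture(img_hi, labels)
        assert hi.contrast > lo.contrast

    def test_flat_interior_contrast_at_quantization_floor(self):
        img, labels = self._img_labels(0.0)
        d = nuclear_texture(img, labels)
        assert d.contrast == 0

    def test_additive_shift_invariance(self):
        img, labels = self._img_labels(0.15)
        shifted = MultichannelImage(nuclear=img.nuclear + 0.02)
        a = nuclear_texture(img, labels)
        b = nuclear_texture(shifted, labels)
        assert a.contrast == pytest.approx(b.contrast, abs=1e-6)
        assert a.energy == pytest.approx(b.energy, abs=1e-6)

    def test_brightness_scale_invariance(self):
        img, labels = self._img_labels(0.1)
        assert img.nuclear.max() * 1.01 <= 1.0  # no clipping involved
        scaled = MultichannelImage(nuclear=img.nuclear * 1.01)
        a = nuclear_texture(img, labels)
        b = nuclear_texture(scaled, labels)
        assert a.contrast == pytest.approx(b.contrast, abs=1e-6)

    def test_uniform_noise_decorrelated(self):
        rng = np.random.default_rng(9)
        raster = rng.random((128, 128))
        glcm = masked_glcm(raster, np.ones((128, 128), bool))
        d = haralick_descriptors(glcm)
        assert abs(d.correlation) <= 0.05


class TestThickness:
    def test_horizontal_bar_width(self):
        mask = np.zeros((64, 128), bool)
        mask[20:31, 10:118] = True  # height 11
        t = wga_thickness(mask)
        assert abs(t.median_thickness - 11) <= 1

    @pytest.mark.parametrize("w", [4, 8])
    def test_voronoi_network_stroke_width(self, w):
        from cardioquant import PhantomSpec, generate_phantom

        _, truth = generate_phantom(PhantomSpec(seed=5, n_nuclei=60, wga_stroke_width=w))
        t = wga_thickness(truth.wga_mask)
        assert abs(t.median_thickness - w) <= 1

    def test_scaling_doubles_thickness(self):
        mask = np.zeros((64, 128), bool)
        mask[20:31, 10:118] = True
        t1 = wga_thickness(mask)
        t2 = wga_thickness(np.kron(mask, np.ones((2, 2), dtype=bool)))
        assert abs(t2.median_thickness - 2 * t1.median_thickness) / (2 * t1.median_thickness) <= 0.15

    def test_invariant_median_le_max(self):
        rng = np.random.default_rng(10)
        mask = rng.random((64, 64)) < 0.4
        mask[30:34, :] = True
        t = wga_thickness(mask)
        assert 0 < t.median_thickness <= t.max_thickness

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateInputError):
            wga_thickness(np.zeros((16, 16), bool))
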