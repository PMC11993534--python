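import numpy as np
import pytest
from scipy import ndimage as ndi

from cardioquant import (
    MultichannelImage,
    PhantomSpec,
    adaptive_threshold,
    generate_phantom,
    segment_matrix,
    segment_nuclei,
    segment_vessels,
    select_threshold_lowpoint,
)
from cardioquant.errors import ParameterError, SegmentationError
from conftest import make_disk


def jaccard(a, b):
    return (a & b).sum() / (a | b).sum()


class TestAdaptiveThreshold:
    def test_constant_raster_gives_empty_mask(self):
        assert not adaptive_threshold(np.full((64, 64), 0.5), 33, 0.1).any()

    def test_bright_disk_recovered_within_boundary_band(self):
        img = np.full((128, 128), 0.1)
        disk = make_disk((128, 128), (64, 64), 20)
        img[disk] = 0.9
        mask = adaptive_threshold(img, 127, 0.1)
        disagree = mask ^ disk
        band = ndi.binary_dilation(disk, iterations=1) & ~ndi.binary_erosion(disk, iterations=1)
        assert np.all(disagree <= band)  # only boundary pixels may differ

    def test_robust_to_illumination_gradient_where_global_fails(self):
        base = np.full((200, 200), 0.1)
        truth = np.zeros((200, 200), dtype=bool)
        for cy in (40, 100, 160):
            for cx in (40, 100, 160):
                d = make_disk((200, 200), (cy, cx), 12)
                truth |= d
        # object contrast (0.25) smaller than the gradient span (0.3): the
        # left-column objects end up dimmer than the right-column background
        base[truth] = 0.35
        gradient = np.tile(np.linspace(0.0, 0.3, 200), (200, 1))
        flat_mask = adaptive_threshold(base, 51, 0.2)
        grad_mask = adaptive_threshold(np.clip(base + gradient, 0, 1), 51, 0.2)
        assert jaccard(flat_mask, grad_mask) >= 0.95
        # a single global threshold cannot serve both ends of the gradient
        shaded = np.clip(base + gradient, 0, 1)
        best_global = max(
            jaccard(shaded > t, truth) for t in np.linspace(0.05, 0.95, 37)
        )
        assert best_global < 0.95

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ParameterError):
            adaptive_threshold(np.zeros((16, 16)), 21, 0.1)

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            adaptive_threshold(np.zeros((32, 32)), 8, 0.1)


@pytest.fixture(scope="module")
def clean_phantom():
    spec = PhantomSpec(seed=11, n_nuclei=40, n_vessels=0, noise_sd=0.0,
                       speckle_amplitude=0.0, gradient_amplitude=0.0)
    return generate_phantom(spec)


class TestLowpointSelection:

    def test_noiseless_phantom_plateau_at_truth(self, clean_phantom):
        img, truth = clean_phantom
        labels, sweep = segment_nuclei(img, exclude_border=False)
        counts = sweep.region_counts
        # a plateau of the curve sits at the true count and is selected
        assert (counts == truth.n_nuclei).sum() >= 5
        assert labels.n_objects == truth.n_nuclei

    def test_salt_noise_gives_u_shape_and_exact_recovery(self):
        spec = PhantomSpec(seed=11, n_nuclei=40, n_vessels=0, semi_major_mean=14,
                           speckle_amplitude=0.25, speckle_corr_length=4,
                           nucleus_intensity=0.7)
        img, truth = generate_phantom(spec)
        rng = np.random.default_rng(123)
        nuc = img.nuclear.copy()
        nuc[rng.random(nuc.shape) < 0.005] = 1.0  # salt: 0.5% pixels at 1.0
        salted = MultichannelImage(nuclear=nuc)
        labels, sweep = segment_nuclei(salted, window=25, exclude_border=False)
        c = sweep.region_counts
        k = int(np.argmin(c))
        assert 0 < k < len(c) - 1
        assert c[0] > c[k] and c[-1] > c[k]  # falls with threshold, rises again
        assert labels.n_objects == truth.n_nuclei

    def test_all_background_image_raises(self):
        with pytest.raises(SegmentationError):
            select_threshold_lowpoint(np.zeros((64, 64)), window=33)

    def test_selection_is_deterministic(self, clean_phantom):
        img, _ = clean_phantom
        pre = img.nuclear
        r1 = select_threshold_lowpoint(pre)
        r2 = select_threshold_lowpoint(pre)
        assert r1.selected_sensitivity == r2.selected_sensitivity
        np.testing.assert_array_equal(r1.region_counts, r2.region_counts)

    def test_too_short_sweep_rejected(self):
        with pytest.raises(ParameterError):
            select_threshold_lowpoint(np.ones((32, 32)) * 0.5, sweep=np.array([0.1, 0.2]))


class TestSegmentNuclei:
    def test_recovers_count_on_80_nucleus_phantom(self):
        img, truth = generate_phantom(PhantomSpec(seed=0, n_nuclei=80))
        labels, _ = segment_nuclei(img)
        assert abs(labels.n_objects - truth.n_nuclei) <= 2

    def test_overlapping_pair_counts_once(self):
        # two overlapping nuclei merge into one 8-connected blob: the known
        # no-watershed limitation, asserted explicitly
        raster = np.full((128, 128), 0.05)
        raster[make_disk((128, 128), (64, 54), 12)] = 0.9
        raster[make_disk((128, 128), (64, 70), 12)] = 0.9
        labels, _ = segment_nuclei(
            MultichannelImage(nuclear=raster), window=63, exclude_border=False
        )
        assert labels.n_objects == 1

    def test_border_touching_nucleus_excluded(self):
        img = np.full((128, 128), 0.05)
        interior = make_disk((128, 128), (64, 64), 10)
        edge = make_disk((128, 128), (0, 64), 10)  # half outside the frame
        raster = img.copy()
        raster[interior | edge] = 0.9
        m = MultichannelImage(nuclear=raster)
        labels, _ = segment_nuclei(m, window=63, exclude_border=True)
        assert labels.n_objects == 1
        labels2, _ = segment_nuclei(m, window=63, exclude_border=False)
        assert labels2.n_objects == 2

    def test_label_areas_partition_foreground(self):
        img, _ = generate_phantom(PhantomSpec(seed=4, n_nuclei=30))
        labels, _ = segment_nuclei(img)
        areas = np.bincount(labels.labels.ravel())[1:]
        assert areas.sum() == labels.mask.sum()
        assert len(areas) == labels.n_objects


class TestSegmentMatrix:
    def test_network_mask_matches_truth(self):
        img, truth = generate_phantom(PhantomSpec(seed=5, n_nuclei=60, wga_stroke_width=8))
        mask = segment_matrix(img)
        assert jaccard(mask, truth.wga_mask) >= 0.9

    def test_all_dark_channel_yields_empty_mask(self, caplog):
        img = MultichannelImage(nuclear=None, matrix=np.zeros((64, 64)))
        with caplog.at_level("WARNING"):
            mask = segment_matrix(img)
        assert not mask.any()
        assert any("empty" in r.message for r in caplog.records)

    def test_brightness_scaling_robustness(self):
        img, _ = generate_phantom(PhantomSpec(seed=6, n_nuclei=60))
        brighter = MultichannelImage(matrix=np.clip(img.matrix * 1.2, 0, 1))
        m1 = segment_matrix(img)
        m2 = segment_matrix(brighter)
        assert (m1 ^ m2).mean() < 0.02  # <2% pixel disagreement


class TestSegmentVessels:
    def test_five_disks_recovered(self):
        img, truth = generate_phantom(PhantomSpec(seed=7, n_nuclei=40, n_vessels=5))
        vessels = segment_vessels(img)
        assert vessels.n_objects == 5

    def test_annulus_counted_once_with_filled_lumen(self):
        raster = np.full((128, 128), 0.05)
        outer = make_disk((128, 128), (64, 64), 20)
        inner = make_disk((128, 128), (64, 64), 8)
        raster[outer & ~inner] = 0.9
        vessels = segment_vessels(MultichannelImage(vessel=raster))
        assert vessels.n_objects == 1
        assert abs(vessels.mask.sum() - outer.sum()) / outer.sum() < 0.1

    def test_small_speck_removed(self):
        raster = np.full((128, 128), 0.05)
        raster[make_disk((128, 128), (30, 30), 15)] = 0.9
        raster[60:62, 60:62] = 0.9  # 4-px speck
        vessels = segment_vessels(MultichannelImage(vessel=raster), min_area=20)
        assert vessels.n_objects == 1
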