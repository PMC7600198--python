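import math

import numpy as np
import pytest

from sdhseg.features import (
    GABOR_COLUMNS,
    HANDCRAFTED_COLUMNS,
    HIST_COLUMNS,
    LOCATION_COLUMNS,
    LOG_COLUMNS,
    GaborParams,
    assemble_feature_table,
    compute_spherical_frame,
    extract_window,
    gabor_bank,
    gabor_kernel,
    histogram_features,
    location_features,
    log_features,
    _smoothness,
)
from sdhseg.phantom import LesionSpec, generate_phantom
from sdhseg.preprocess import compute_head_masks
from sdhseg.superpixel import generate_superpixels, label_superpixels
from tests.conftest import small_config


class TestSmoothness:
    def test_zero_for_flat_patch(self):
        assert _smoothness(np.full((25, 25), 42.0)) == 0.0

    def test_monotone_in_sigma(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 1, size=(25, 25))
        values = [
            _smoothness(50.0 + s * (base - 0.5) * 100.0) for s in (0.1, 0.3, 0.6, 1.0)
        ]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_approaches_one_for_large_sigma(self):
        # half 0 HU / half 100 HU: rescaled variance 0.25 -> R = 0.2
        patch = np.zeros((2, 10))
        patch[1] = 100.0
        assert _smoothness(patch) == pytest.approx(1 - 1 / 1.25)


class TestHistogramFeatures:
    def test_flat_patch_degenerate_stats(self):
        f = dict(zip(HIST_COLUMNS, histogram_features(np.full((25, 25), 40.0), np.full(9, 40.0))))
        assert f["hist_sd"] == 0.0
        assert f["smoothness"] == 0.0
        assert f["hist_entropy"] == 0.0
        assert f["hist_skew"] == 0.0 and f["hist_kurt"] == 0.0

    def test_two_level_patch_closed_form(self):
        # half 5 HU / half 95 HU: two occupied bins -> entropy exactly 1 bit
        patch = np.zeros((2, 16))
        patch[0] = 5.0
        patch[1] = 95.0
        f = dict(zip(HIST_COLUMNS, histogram_features(patch, patch.ravel())))
        assert f["hist_entropy"] == pytest.approx(1.0)
        assert f["hist_mean"] == pytest.approx(50.0)
        assert f["hist_sd"] == pytest.approx(45.0)  # direct formula, half/half
        assert f["sp_mean"] == pytest.approx(50.0)
        assert f["hist_min"] == 5.0 and f["hist_max"] == 95.0

    def test_superpixel_mean_separate_from_window(self):
        patch = np.full((25, 25), 40.0)
        f = dict(zip(HIST_COLUMNS, histogram_features(patch, np.full(5, 70.0))))
        assert f["sp_mean"] == pytest.approx(70.0)
        assert f["hist_mean"] == pytest.approx(40.0)


class TestGabor:
    def test_kernel_is_one_at_origin(self):
        for orient in (0.0, math.pi / 8, 3 * math.pi / 4):
            k = gabor_kernel(GaborParams(u0=0.25, sigma_x=2.0, sigma_y=2.0, orientation=orient))
            center = tuple(s // 2 for s in k.shape)
            assert k[center] == pytest.approx(1.0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            GaborParams(u0=-1.0, sigma_x=1.0, sigma_y=1.0)
        with pytest.raises(ValueError):
            GaborParams(u0=0.1, sigma_x=1.0, sigma_y=1.0, orientation=math.pi)

    def test_constant_image_equal_across_orientations(self):
        # zero-DC kernels: constant x kernel sum = 0 for every filter
        img = np.full((64, 64), 3.0)
        bank = gabor_bank(img)  # (32, H, W) magnitude responses
        center = bank[:, 28:36, 28:36].mean(axis=(1, 2))
        per_wavelength = center.reshape(4, 8)
        for row in per_wavelength:
            np.testing.assert_allclose(row, row[0], atol=1e-9)
        np.testing.assert_allclose(center, 0.0, atol=1e-9)

    def test_orientation_selectivity_on_grating(self):
        """A vertical grating at 8 px/cycle peaks at the aligned orientation
        of the aligned wavelength, checked against all 32 responses."""
        cc = np.mgrid[0:96, 0:96][1]
        grating = np.cos(2 * np.pi * cc / 8.0)
        label = np.zeros((96, 96), dtype=np.int32)
        label[40:56, 40:56] = 1
        feats = gabor_bank(grating, label)[0]
        names = np.array(GABOR_COLUMNS)
        best = names[int(np.argmax(feats))]
        assert best == "gabor_o0_w8"

    def test_rotated_grating_moves_peak_orientation(self):
        rr, cc = np.mgrid[0:96, 0:96]
        diag = np.cos(2 * np.pi * (cc * math.cos(math.pi / 4) + rr * math.sin(math.pi / 4)) / 8.0)
        label = np.zeros((96, 96), dtype=np.int32)
        label[40:56, 40:56] = 1
        feats = gabor_bank(diag, label)[0].reshape(4, 8)
        w8 = feats[2]  # wavelength 8 row
        assert int(np.argmax(w8)) == 2  # orientation pi/4 = index 2


class TestLoG:
    def test_constant_image_zero(self):
        img = np.full((48, 48), 9.0)
        label = np.zeros((48, 48), dtype=np.int32)
        label[20:28, 20:28] = 1
        np.testing.assert_allclose(log_features(img, label)[0], 0.0, atol=1e-8)

    def test_linear_ramp_zero_interior(self):
        img = np.mgrid[0:64, 0:64][1].astype(float)
        label = np.zeros((64, 64), dtype=np.int32)
        label[28:36, 28:36] = 1
        feats = log_features(img, label)[0]
        np.testing.assert_allclose(feats[:3], 0.0, atol=1e-6)

    def test_step_edge_changes_sign(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 100.0
        label = np.zeros((64, 64), dtype=np.int32)
        label[28:36, 26:30] = 1  # dark side of the edge
        label[28:36, 34:38] = 2  # bright side
        feats = log_features(img, label)
        assert feats[0][1] * feats[1][1] < 0  # sigma=2 response flips sign


class TestWindow:
    def test_25px_window_has_625_pixels(self):
        patch = extract_window(np.zeros((60, 60)), (30, 30), size=25)
        assert patch.size == 625

    def test_interior_crop_equals_unpadded(self, rng):
        img = rng.normal(size=(60, 60))
        patch = extract_window(img, (30, 30), size=25)
        np.testing.assert_array_equal(patch, img[18:43, 18:43])

    def test_out_of_support_errors(self):
        validity = np.zeros((60, 60), dtype=bool)
        validity[20:40, 20:40] = True
        with pytest.raises(ValueError, match="padded support"):
            extract_window(np.zeros((60, 60)), (21, 30), size=25, validity=validity)


class TestLocation:
    @pytest.fixture(scope="class")
    def frame_setup(self, request):
        cfg = small_config(seed=11, scan_id="loc")
        volume, _, _ = generate_phantom(cfg)
        masks = compute_head_masks(volume)
        frame = compute_spherical_frame(masks, volume)
        return volume, masks, frame

    def test_origin_has_zero_radius(self, frame_setup):
        volume, masks, frame = frame_setup
        loc = location_features(frame.origin_voxel, masks, volume, frame)
        assert loc.r == pytest.approx(0.0, abs=1e-9)
        assert loc.phi == 0.0 and loc.theta == 0.0

    def test_same_plane_zero_elevation(self, frame_setup):
        volume, masks, frame = frame_setup
        r0, c0, k0 = frame.origin_voxel
        point = (r0, c0 + 10, k0)
        loc = location_features(point, masks, volume, frame)
        assert loc.phi == pytest.approx(0.0, abs=1e-9)
        assert loc.r == pytest.approx(10 * volume.spacing[1])

    def test_mirrored_points_opposite_azimuth(self, frame_setup):
        volume, masks, frame = frame_setup
        r0, c0, k0 = frame.origin_voxel
        left = location_features((r0, c0 + 12, k0), masks, volume, frame)
        right = location_features((r0, c0 - 12, k0), masks, volume, frame)
        assert left.theta == pytest.approx(-right.theta, abs=0.02)
        assert abs(left.theta) > 0.5

    def test_outside_intracranial_errors(self, frame_setup):
        volume, masks, frame = frame_setup
        with pytest.raises(ValueError, match="intracranial"):
            location_features((0.0, 0.0, 0.0), masks, volume, frame)


class TestAssembly:
    def test_handcrafted_block_is_51_columns(self):
        assert len(HANDCRAFTED_COLUMNS) == 9 + 32 + 5 + 4 + 1

    @pytest.fixture(scope="class")
    def table_setup(self):
        cfg = small_config(
            lesions=(LesionSpec(type="acute", target_volume_cc=10.0),),
            seed=21,
            patient_age=63.0,
            scan_id="assembly",
        )
        volume, gt, _ = generate_phantom(cfg)
        masks = compute_head_masks(volume)
        spmap = generate_superpixels(volume, masks.roi_band)
        labels = label_superpixels(spmap, gt)
        table = assemble_feature_table(volume, masks, spmap, labels=labels)
        return volume, masks, spmap, table

    def test_one_row_per_superpixel(self, table_setup):
        _, _, spmap, table = table_setup
        assert len(table) == spmap.n_superpixels

    def test_no_missing_values(self, table_setup):
        *_, table = table_setup
        assert not table[HANDCRAFTED_COLUMNS].isna().any().any()

    def test_age_constant_within_scan(self, table_setup):
        *_, table = table_setup
        assert (table["age"] == 63.0).all()

    def test_deterministic_bit_identical(self, table_setup):
        volume, masks, spmap, table = table_setup
        again = assemble_feature_table(volume, masks, spmap, labels=None, age=63.0)
        np.testing.assert_array_equal(
            table[HANDCRAFTED_COLUMNS].to_numpy(), again[HANDCRAFTED_COLUMNS].to_numpy()
        )

    def test_features_invariant_to_skull_intensity(self):
        """Filter features come from skull-free mirror-padded slices, so
        changing the skull HU must leave every feature untouched."""
        base = small_config(
            lesions=(LesionSpec(type="acute", target_volume_cc=10.0),),
            seed=33,
            patient_age=50.0,
        )
        tables = []
        for skull_hu in (900.0, 1400.0):
            from dataclasses import replace

            cfg = replace(base, skull_hu=skull_hu)
            volume, gt, _ = generate_phantom(cfg)
            masks = compute_head_masks(volume)
            spmap = generate_superpixels(volume, masks.roi_band)
            tables.append(assemble_feature_table(volume, masks, spmap, age=50.0))
        np.testing.assert_allclose(
            tables[0][HANDCRAFTED_COLUMNS].to_numpy(),
            tables[1][HANDCRAFTED_COLUMNS].to_numpy(),
            rtol=1e-9,
        )
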