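"""Mask-derived morphometry against brute-force geometric oracles."""

import math

import numpy as np
import pytest

from conftest import disk_mask, ellipse_mask
from orbitmorph import (LabeledVolume, PhantomSpec, VoxelGeometry, aed,
                        clean_prediction, eyeball_volume, feret_diameters,
                        make_phantom, measure_volume, nerve_centroid, onsd,
                        slice_area)


def caliper_oracle(mask, geom, n_angles=3600):
    """Brute-force min/max caliper widths on the half-level boundary:
    max pairwise distance over all contour points, and min projection
    extent over a fine sweep of directions.  Independent of the
    hull-based caliper implementation it checks."""
    from skimage.measure import find_contours

    rc = np.vstack(find_contours(np.pad(mask, 1).astype(float), 0.5)) - 1.0
    pts = np.column_stack([rc[:, 1] * geom.sx, rc[:, 0] * geom.sy])
    diff = pts[:, None, :] - pts[None, :, :]
    longest = float(np.sqrt((diff ** 2).sum(-1)).max())
    thetas = np.linspace(0, np.pi, n_angles, endpoint=False)
    dirs = np.column_stack([np.cos(thetas), np.sin(thetas)])
    proj = pts @ dirs.T
    shortest = float((proj.max(0) - proj.min(0)).min())
    return longest, shortest


class TestSliceArea:
    def test_pixel_count_times_spacing(self, geometry):
        mask = np.zeros((20, 20), bool)
        mask.flat[:100] = True
        assert slice_area(mask, geometry) == pytest.approx(100 * 0.25)

    def test_empty_slice_is_zero(self, geometry):
        assert slice_area(np.zeros((5, 5), bool), geometry) == 0.0

    def test_digitized_disk_matches_pixel_oracle(self):
        geom = VoxelGeometry(1.0, 1.0, 3.0)
        mask = disk_mask((32, 32), (16, 16), 10)
        area = slice_area(mask, geom)
        assert area == int(mask.sum())  # exact pixel-count equality
        assert abs(area - math.pi * 100) / (math.pi * 100) < 0.05


class TestEyeballVolume:
    def test_single_slice_arithmetic(self, geometry):
        labels = np.zeros((1, 20, 20), np.uint8)
        labels[0].flat[:100] = 1  # 100 px * 0.25 mm2 = 25 mm2; * 3 mm = 75 mm3
        assert eyeball_volume(labels, geometry) == pytest.approx(0.075)

    def test_empty_volume_warns_and_returns_zero(self, geometry):
        with pytest.warns(UserWarning, match="no eyeball"):
            assert eyeball_volume(np.zeros((2, 4, 4), np.uint8), geometry) == 0.0

    def test_phantom_sphere_volume(self, geometry):
        vol, truth = make_phantom(PhantomSpec(eyeball_radius=12.0, noise_sd=0.0))
        v = eyeball_volume(vol.labels, geometry)
        # exactly voxel count x voxel volume
        assert v == pytest.approx(
            (vol.labels == 1).sum() * geometry.voxel_volume_mm3 / 1000.0)
        assert abs(v - truth.analytic_volume_cm3) / truth.analytic_volume_cm3 < 0.05


class TestFeretDiameters:
    def test_disk_both_diameters_close(self):
        geom = VoxelGeometry(1.0, 1.0, 3.0)
        mask = disk_mask((16, 16), (8, 8), 2.0)  # diameter 4 mm
        d = feret_diameters(mask, geom)
        assert d.longest == pytest.approx(4.0, abs=1.0)
        assert d.shortest == pytest.approx(4.0, abs=1.0)

    def test_single_pixel_floored_at_spacing(self, geometry):
        mask = np.zeros((8, 8), bool)
        mask[3, 4] = True
        d = feret_diameters(mask, geometry)
        assert d.longest == d.shortest == geometry.in_plane_max

    def test_collinear_pixels(self, geometry):
        mask = np.zeros((8, 8), bool)
        mask[4, 1:6] = True  # 5-px row at 0.5 mm: capsule contour 5 x 1 px
        d = feret_diameters(mask, geometry)
        assert d.longest == pytest.approx(2.5)
        assert d.shortest == pytest.approx(0.5)

    @pytest.mark.parametrize("theta_deg", [0, 17, 45, 83, 130])
    def test_ellipse_matches_brute_force_caliper_oracle(self, theta_deg):
        geom = VoxelGeometry(1.0, 1.0, 3.0)
        mask = ellipse_mask((24, 24), (12, 12), semi_r=1.0, semi_c=3.0,
                            theta=math.radians(theta_deg))
        d = feret_diameters(mask, geom)
        longest_o, shortest_o = caliper_oracle(mask, geom)
        assert d.longest == pytest.approx(longest_o, abs=1e-9)
        # the exact min width can only sit at or just below the angle sweep
        assert shortest_o - 5e-3 <= d.shortest <= shortest_o + 1e-9
        # 6 x 2 mm ellipse within one pixel spacing
        assert d.longest == pytest.approx(6.0, abs=1.0)
        assert d.shortest == pytest.approx(2.0, abs=1.0)

    def test_empty_slice_rejected(self, geometry):
        with pytest.raises(ValueError, match="empty"):
            feret_diameters(np.zeros((4, 4), bool), geometry)


class TestNerveCentroid:
    def test_symmetric_disk_center(self):
        geom = VoxelGeometry(0.5, 0.5, 3.0)
        mask = disk_mask((32, 32), (16, 16), 5)
        assert nerve_centroid(mask, geom) == pytest.approx((8.0, 8.0))

    def test_single_pixel(self, geometry):
        mask = np.zeros((10, 10), bool)
        mask[7, 3] = True
        assert nerve_centroid(mask, geometry) == (3 * 0.5, 7 * 0.5)

    def test_l_shaped_blob_equals_enumeration(self, geometry):
        mask = np.zeros((10, 10), bool)
        pixels = [(2, 2), (3, 2), (4, 2), (4, 3), (4, 4)]
        for r, c in pixels:
            mask[r, c] = True
        cx = np.mean([c * geometry.sx for _, c in pixels])
        cy = np.mean([r * geometry.sy for r, _ in pixels])
        assert nerve_centroid(mask, geometry) == pytest.approx((cx, cy))


def tube_labels(centers_px, radius_px, shape=(32, 32), n_slices=None):
    """Label stack with a class-2 disk per listed slice center (px units)."""
    n_slices = n_slices or len(centers_px)
    labels = np.zeros((n_slices, *shape), np.uint8)
    for k, ctr in enumerate(centers_px):
        if ctr is not None:
            labels[k][disk_mask(shape, ctr, radius_px)] = 2
    return labels


class TestOnsd:
    def test_circular_tube_first_equals_second(self):
        geom = VoxelGeometry(1.0, 1.0, 3.0)
        labels = tube_labels([(16, 16), (16, 16)], radius_px=2.0)
        res = onsd(labels, geom)
        assert res.first_slice == 0 and res.second_slice == 1
        assert res.first_cm == pytest.approx(0.4, abs=0.1)
        assert res.second_cm == pytest.approx(res.first_cm)

    def test_single_slice_second_missing(self):
        geom = VoxelGeometry(1.0, 1.0, 3.0)
        labels = tube_labels([(16, 16), None, None], radius_px=2.0, n_slices=3)
        res = onsd(labels, geom)
        assert res.second_cm is None and res.second_slice is None

    def test_elliptical_first_slice_mean_diameter(self):
        geom = VoxelGeometry(1.0, 1.0, 3.0)
        labels = np.zeros((2, 24, 24), np.uint8)
        labels[0][ellipse_mask((24, 24), (12, 12), semi_r=1.0, semi_c=3.0)] = 2
        labels[1][disk_mask((24, 24), (12, 12), 2.0)] = 2
        res = onsd(labels, geom)
        longest_o, shortest_o = caliper_oracle(labels[0] == 2, geom)
        assert res.first_cm == pytest.approx(
            (longest_o + shortest_o) / 2 / 10, abs=1e-3)
        assert res.first_cm == pytest.approx(0.4, abs=0.1)

    def test_reverse_slices_flag_flips_scan_order(self):
        geom = VoxelGeometry(1.0, 1.0, 3.0)
        labels = np.zeros((3, 24, 24), np.uint8)
        labels[0][ellipse_mask((24, 24), (12, 12), 1.0, 3.0)] = 2
        labels[2][disk_mask((24, 24), (12, 12), 2.0)] = 2
        fwd = onsd(labels, geom)
        rev = onsd(labels, geom, reverse_slices=True)
        assert fwd.first_slice == 0
        assert rev.first_slice == 2
        assert rev.second_cm is None  # slice 1 has no nerve

    def test_no_nerve_rejected(self, geometry):
        with pytest.raises(ValueError, match="no optic-nerve"):
            onsd(np.zeros((3, 8, 8), np.uint8), geometry)


class TestAed:
    def test_straight_tube_axial_only(self):
        geom = VoxelGeometry(1.0, 1.0, 3.0)
        labels = tube_labels([(16, 16)] * 5, radius_px=2.0)
        assert aed(labels, geom) == pytest.approx(1.2)  # n=4, 4*3mm = 12mm

    def test_pythagorean_triple(self):
        geom = VoxelGeometry(1.0, 1.0, 3.0)
        # centroid moves 3 mm in x and 4 mm in y over 5 slices (n = 4)
        labels = tube_labels([(10, 10), None, None, None, (14, 13)],
                             radius_px=2.0)
        labels[1][disk_mask((32, 32), (11, 11), 2.0)] = 2
        labels[2][disk_mask((32, 32), (12, 12), 2.0)] = 2
        labels[3][disk_mask((32, 32), (13, 12), 2.0)] = 2
        assert aed(labels, geom) == pytest.approx(1.3)  # sqrt(9+16+144)/10

    def test_oblique_phantom_tube_matches_analytic_endpoints(self, geometry):
        path = tuple((1.1 * i, -0.7 * i) for i in range(3))
        spec = PhantomSpec(nerve_path=path, noise_sd=0.0)
        vol, truth = make_phantom(spec)
        assert aed(vol.labels, geometry) == pytest.approx(
            truth.analytic_aed_cm, abs=geometry.in_plane_max / 10)

    def test_axial_term_is_lower_bound(self, small_cohort):
        for m in small_cohort[:6]:
            n = m.spec.nerve_end_slice - m.spec.nerve_start_slice
            assert aed(m.volume.labels, m.volume.geometry) >= n * 3.0 / 10 - 1e-9


class TestCleanPrediction:
    def test_single_component_unchanged(self, default_phantom):
        vol, _ = default_phantom
        np.testing.assert_array_equal(clean_prediction(vol.labels), vol.labels)

    def test_small_second_blob_removed(self, geometry):
        labels = np.zeros((3, 16, 16), np.uint8)
        labels[1, 4:9, 4:9] = 1          # 25-voxel blob
        labels[0, 14:16, 14:16] = 1      # 4-voxel blob, disconnected
        cleaned = clean_prediction(labels)
        assert (cleaned[0] == 0).all()
        np.testing.assert_array_equal(cleaned[1], labels[1])

    def test_speckle_does_not_change_measurements(self, geometry):
        vol, _ = make_phantom(PhantomSpec(noise_sd=0.0))
        noisy = vol.labels.copy()
        rng = np.random.default_rng(0)
        for cls in (1, 2):  # sprinkle far-corner speckles
            for _ in range(5):
                z = rng.integers(0, 12)
                if noisy[z, 62, 62] == 0:
                    noisy[z, 62, 62] = cls
        cleaned = clean_prediction(noisy)
        ref = measure_volume(vol)
        got = measure_volume(LabeledVolume(vol.intensities, geometry, cleaned))
        assert got.volume_cm3 == pytest.approx(ref.volume_cm3)
        assert got.onsd_first_cm == pytest.approx(ref.onsd_first_cm)
        assert got.aed_cm == pytest.approx(ref.aed_cm)


class TestRecovery:
    """Measurement on TRUE phantom labels recovers the analytic truth."""

    def test_cohort_parameter_recovery(self, small_cohort):
        for m in small_cohort:
            rec = measure_volume(m.volume, source="truth")
            t = m.truth
            assert abs(rec.volume_cm3 - t.analytic_volume_cm3) \
                / t.analytic_volume_cm3 < 0.05
            tol_cm = m.volume.geometry.in_plane_max / 10
            assert abs(rec.onsd_first_cm - t.analytic_onsd_first_cm) <= tol_cm
            if t.analytic_onsd_second_cm is not None:
                assert abs(rec.onsd_second_cm - t.analytic_onsd_second_cm) <= tol_cm
            assert abs(rec.aed_cm - t.analytic_aed_cm) <= tol_cm

    def test_volume_invariant_under_orbit_split(self):
        from orbitmorph import split_orbits
        spec = PhantomSpec(grid_shape=(32, 32, 12),
                           eyeball_center=(8.0, 8.0, 11.3), eyeball_radius=7.0,
                           nerve_start_slice=7, nerve_end_slice=11,
                           nerve_path=((0.0, 0.0),) * 5,
                           nerve_diameter_profile=((4.0, 3.0),) * 5,
                           noise_sd=0.0)
        right, _ = make_phantom(spec)
        wide = LabeledVolume(
            np.concatenate([right.intensities,
                            np.zeros_like(right.intensities)], axis=2),
            right.geometry,
            np.concatenate([right.labels, np.zeros_like(right.labels)], axis=2))
        r, l = split_orbits(wide)
        assert eyeball_volume(r.labels, r.geometry) == pytest.approx(
            eyeball_volume(wide.labels, wide.geometry))
        assert (l.labels == 1).sum() == 0

    @pytest.mark.parametrize("theta", [0.0, 20.0, 45.0, 75.0])
    def test_onsd_rotation_invariance(self, geometry, theta):
        spec = PhantomSpec(noise_sd=0.0,
                           nerve_rotation_deg=(theta,) * 3)
        vol, truth = make_phantom(spec)
        res = onsd(vol.labels, geometry)
        assert res.first_cm == pytest.approx(
            truth.analytic_onsd_first_cm, abs=geometry.in_plane_max / 10)
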