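"""DICOM I/O, threshold segmentation, slice editing/interpolation, surface
extraction and smoothing."""

import numpy as np
import pytest

from thermofuse.volume import (
    DicomSeriesError,
    SegmentationMask,
    VolumeImage,
    cleanup_mask,
    edit_mask,
    extract_surface,
    interpolate_slices,
    load_dicom_series,
    smooth_mesh,
    threshold_mask,
    write_dicom_series,
)


def sphere_mask(r_mm=10.0, spacing=1.0, pad=3):
    n = int(2 * (r_mm / spacing + pad)) + 1
    c = (n - 1) / 2.0
    zz, yy, xx = np.mgrid[:n, :n, :n]
    m = ((xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2) * spacing**2 <= r_mm**2
    return SegmentationMask(m, "sphere", (spacing,) * 3)


class TestDicomSeries:
    def test_round_trip(self, tmp_path, rng):
        vol = VolumeImage(
            np.round(rng.uniform(-1000, 1000, (8, 16, 12))),
            (0.7, 0.8, 1.1),
            origin=[5.0, -3.0, 10.0],
        )
        write_dicom_series(vol, tmp_path / "series")
        back = load_dicom_series(tmp_path / "series")
        np.testing.assert_array_equal(back.voxels, vol.voxels)
        np.testing.assert_allclose(back.spacing, vol.spacing)
        np.testing.assert_allclose(back.origin, vol.origin)

    def test_shuffled_file_names_sorted_by_position(self, tmp_path, rng):
        vol = VolumeImage(np.round(rng.uniform(0, 100, (6, 8, 8))), (1.0, 1.0, 2.0))
        d = tmp_path / "series"
        paths = write_dicom_series(vol, d)
        # scramble the on-disk names; the loader must sort by slice position
        order = rng.permutation(len(paths))
        for p, k in zip(paths, order):
            p.rename(d / f"x_{k:02d}.dcm")
        back = load_dicom_series(d)
        np.testing.assert_array_equal(back.voxels, vol.voxels)

    def test_mixed_series_rejected(self, tmp_path, rng):
        vol = VolumeImage(np.zeros((3, 4, 4)), (1, 1, 1))
        d = tmp_path / "series"
        write_dicom_series(vol, d, series_uid="1.2.3.1")
        sub = tmp_path / "other"
        ps = write_dicom_series(vol, sub, series_uid="1.2.3.2")
        ps[0].rename(d / "intruder.dcm")
        with pytest.raises(DicomSeriesError):
            load_dicom_series(d)

    def test_empty_directory_rejected(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(DicomSeriesError):
            load_dicom_series(tmp_path / "empty")


class TestThresholdMask:
    def test_single_voxel_window(self):
        vol = VolumeImage(np.zeros((5, 5, 5)), (1, 1, 1))
        vol.voxels[2, 3, 1] = 100.0
        m = threshold_mask(vol, 50, 200)
        assert m.count() == 1
        assert m.voxels[2, 3, 1]

    def test_full_range_equals_roi(self):
        vol = VolumeImage(np.arange(60.0).reshape(3, 4, 5), (1, 1, 1))
        roi = (slice(1, 3), slice(0, 2), slice(2, 5))
        m = threshold_mask(vol, -1e9, 1e9, roi=roi)
        box = np.zeros((3, 4, 5), bool)
        box[roi] = True
        np.testing.assert_array_equal(m.voxels, box)

    def test_agrees_with_exhaustive_scan(self, rng):
        """Oracle: triple-loop voxel scan on random volumes."""
        for _ in range(5):
            vox = rng.uniform(-100, 100, (4, 5, 6))
            vol = VolumeImage(vox, (1, 1, 1))
            lo, hi = sorted(rng.uniform(-80, 80, 2))
            m = threshold_mask(vol, lo, hi)
            expected = np.zeros(vox.shape, bool)
            for i in range(4):
                for j in range(5):
                    for k in range(6):
                        expected[i, j, k] = lo <= vox[i, j, k] <= hi
            np.testing.assert_array_equal(m.voxels, expected)

    def test_inverted_window_rejected(self):
        vol = VolumeImage(np.zeros((2, 2, 2)), (1, 1, 1))
        with pytest.raises(ValueError):
            threshold_mask(vol, 10, -10)


class TestEditMask:
    @pytest.fixture
    def mask(self):
        return SegmentationMask(np.zeros((8, 32, 32), bool), "m", (1, 1, 1))

    def test_add_then_remove_is_identity(self, mask):
        brush = {"disk": ((16, 16), 5)}
        added = edit_mask(mask, (2, 5), "add", brush)
        removed = edit_mask(added, (2, 5), "remove", brush)
        np.testing.assert_array_equal(removed.voxels, mask.voxels)

    def test_slices_outside_range_untouched(self, mask):
        out = edit_mask(mask, (3, 5), "add", {"disk": ((16, 16), 4)})
        assert out.voxels[[0, 1, 2, 6, 7]].sum() == 0
        assert out.voxels[3].sum() > 0

    def test_idempotent(self, mask):
        brush = {"polygon": [(5, 5), (5, 20), (20, 20)]}
        once = edit_mask(mask, (0, 2), "add", brush)
        twice = edit_mask(once, (0, 2), "add", brush)
        np.testing.assert_array_equal(once.voxels, twice.voxels)

    def test_out_of_range_slices_rejected(self, mask):
        with pytest.raises(IndexError):
            edit_mask(mask, (5, 9), "add", {"disk": ((4, 4), 2)})


class TestInterpolateSlices:
    def _disk_slice(self, shape, r):
        c = (shape[0] // 2, shape[1] // 2)
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        return (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= r**2

    def test_equal_shapes_copied_to_gap(self):
        vox = np.zeros((3, 32, 32), bool)
        disk = self._disk_slice((32, 32), 6)
        vox[0] = vox[2] = disk
        m = SegmentationMask(vox, "m", (1, 1, 1))
        out = interpolate_slices(m, [0, 2])
        np.testing.assert_array_equal(out.voxels[1], disk)

    def test_radius_interpolates_between_annotations(self):
        vox = np.zeros((5, 48, 48), bool)
        vox[0] = self._disk_slice((48, 48), 5)
        vox[4] = self._disk_slice((48, 48), 9)
        m = SegmentationMask(vox, "m", (1, 1, 1))
        out = interpolate_slices(m, [0, 4])
        # distance-field interpolation: slice 2 carries a disk of radius ~7
        area = out.voxels[2].sum()
        assert np.pi * 6**2 <= area <= np.pi * 8**2

    def test_annotated_slices_unchanged(self):
        vox = np.zeros((4, 24, 24), bool)
        vox[0] = self._disk_slice((24, 24), 4)
        vox[3] = self._disk_slice((24, 24), 7)
        m = SegmentationMask(vox, "m", (1, 1, 1))
        out = interpolate_slices(m, [0, 3])
        np.testing.assert_array_equal(out.voxels[0], vox[0])
        np.testing.assert_array_equal(out.voxels[3], vox[3])

    def test_identity_when_all_slices_annotated(self):
        vox = np.stack([self._disk_slice((24, 24), r) for r in (4, 5, 6)])
        m = SegmentationMask(vox, "m", (1, 1, 1))
        out = interpolate_slices(m, [0, 1, 2])
        np.testing.assert_array_equal(out.voxels, vox)

    def test_too_few_annotations_rejected(self):
        m = SegmentationMask(np.ones((3, 8, 8), bool), "m", (1, 1, 1))
        with pytest.raises(ValueError):
            interpolate_slices(m, [1])


class TestExtractSurface:
    def test_sphere_area_and_volume(self):
        mesh = extract_surface(sphere_mask(r_mm=10.0, spacing=1.0))
        assert mesh.area == pytest.approx(4 * np.pi * 100, rel=0.05)
        assert mesh.volume == pytest.approx(4 / 3 * np.pi * 1000, rel=0.05)

    def test_sphere_is_closed_genus_zero(self):
        mesh = extract_surface(sphere_mask())
        assert mesh.is_watertight
        assert mesh.euler_number == 2

    def test_single_voxel_mesh_contains_voxel_center(self):
        vox = np.zeros((5, 5, 5), bool)
        vox[2, 2, 2] = True
        m = SegmentationMask(vox, "v", (1.0, 1.0, 1.0), origin=[10.0, 20.0, 30.0])
        mesh = extract_surface(m)
        assert mesh.is_watertight
        center = np.array([10.0 + 2, 20.0 + 2, 30.0 + 2])
        lo, hi = np.asarray(mesh.bounds)
        assert (lo < center).all() and (center < hi).all()
        assert mesh.volume > 0

    def test_empty_mask_rejected(self):
        m = SegmentationMask(np.zeros((3, 3, 3), bool), "e", (1, 1, 1))
        with pytest.raises(ValueError):
            extract_surface(m)

    def test_box_volume_recovered(self):
        vox = np.zeros((20, 20, 20), bool)
        vox[2:18, 3:17, 2:16] = True
        mesh = extract_surface(SegmentationMask(vox, "b", (1, 1, 1)))
        assert mesh.volume == pytest.approx(16 * 14 * 14, rel=0.10)


class TestSmoothMesh:
    def test_zero_iterations_identity(self):
        mesh = extract_surface(sphere_mask())
        out = smooth_mesh(mesh, iterations=0)
        np.testing.assert_array_equal(np.asarray(out.vertices), np.asarray(mesh.vertices))

    def test_noise_reduced_on_jittered_sphere(self, rng):
        mesh = extract_surface(sphere_mask(r_mm=10.0))
        noisy = mesh.copy()
        noisy.vertices = np.asarray(noisy.vertices) + rng.normal(scale=0.3, size=noisy.vertices.shape)
        center = noisy.vertices.mean(axis=0)
        dev0 = np.abs(np.linalg.norm(np.asarray(noisy.vertices) - center, axis=1) - 10.0).mean()
        sm = smooth_mesh(noisy)
        dev1 = np.abs(np.linalg.norm(np.asarray(sm.vertices) - center, axis=1) - 10.0).mean()
        assert dev1 < dev0

    def test_volume_drift_within_five_percent(self):
        mesh = extract_surface(sphere_mask(r_mm=10.0))
        sm = smooth_mesh(mesh)  # Taubin defaults
        assert abs(sm.volume - mesh.volume) / mesh.volume <= 0.05

    def test_connectivity_preserved(self):
        mesh = extract_surface(sphere_mask())
        sm = smooth_mesh(mesh, iterations=5)
        assert len(sm.vertices) == len(mesh.vertices)
        np.testing.assert_array_equal(np.asarray(sm.faces), np.asarray(mesh.faces))

    def test_positive_mu_rejected(self):
        mesh = extract_surface(sphere_mask())
        with pytest.raises(ValueError):
            smooth_mesh(mesh, mu_pass=0.5)


class TestCleanupMask:
    def test_keeps_largest_component(self):
        vox = np.zeros((10, 10, 10), bool)
        vox[1:7, 1:7, 1:7] = True  # large blob
        vox[8, 8, 8] = True  # speck
        m = cleanup_mask(SegmentationMask(vox, "m", (1, 1, 1)), closing_radius=0)
        assert not m.voxels[8, 8, 8]
        assert m.voxels[3, 3, 3]
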