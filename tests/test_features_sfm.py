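"""Feature detection/matching and the structure-from-motion estimators,
checked against constructed scenes with known ground truth."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.spatial.transform import Rotation

from thermofuse.camera import CameraIntrinsics, CameraPose
from thermofuse.features import FeatureSet, MatchSet, detect_features, match_features
from thermofuse.sfm import (
    DegenerateMotionError,
    InsufficientDataError,
    SfmConfig,
    SparseCloud,
    bundle_adjust,
    densify,
    estimate_relative_pose,
    filter_matches_ransac,
    initialize_two_view,
    register_next_view,
    reprojection_rmse,
    triangulate,
)
from thermofuse.transforms import umeyama

INTR = CameraIntrinsics(fx=500.0, fy=500.0, cx=160.0, cy=120.0)


def two_view_scene(rng, n=60, pixel_noise=0.0, baseline=0.6):
    """Random 3D points in front of two known cameras with exact (or
    noise-perturbed) projections and shared random unit descriptors."""
    pose_a = CameraPose(np.eye(3), np.zeros(3))
    R = Rotation.from_rotvec([0.0, -0.12, 0.02]).as_matrix()
    center_b = np.array([baseline, 0.0, 0.05])
    pose_b = CameraPose(R, -R @ center_b)
    pts = np.column_stack(
        [rng.uniform(-1.0, 1.0, n), rng.uniform(-0.8, 0.8, n), rng.uniform(4.0, 6.0, n)]
    )
    pix_a = INTR.project(pose_a.transform(pts))
    pix_b = INTR.project(pose_b.transform(pts))
    if pixel_noise:
        pix_a = pix_a + rng.normal(0, pixel_noise, pix_a.shape)
        pix_b = pix_b + rng.normal(0, pixel_noise, pix_b.shape)
    desc = rng.normal(size=(n, 32))
    desc /= np.linalg.norm(desc, axis=1, keepdims=True)
    fa = FeatureSet(pix_a, np.ones(n), desc)
    fb = FeatureSet(pix_b, np.ones(n), desc.copy())
    matches = MatchSet(np.column_stack([np.arange(n), np.arange(n)]))
    return pose_a, pose_b, pts, fa, fb, matches


class TestDetectFeatures:
    def test_blank_image_yields_no_features(self):
        assert len(detect_features(np.full((64, 64), 128, np.uint8))) == 0

    def test_gaussian_blob_detected_at_center(self):
        img = np.zeros((64, 64))
        img[32, 32] = 1.0
        img = gaussian_filter(img, 3.0)
        img = (img / img.max() * 255).astype(np.uint8)
        feats = detect_features(img)
        assert len(feats) >= 1
        d = np.linalg.norm(feats.positions - [32, 32], axis=1)
        assert d.min() <= 2.0

    def test_keypoints_survive_quarter_rotation(self, rng):
        img = gaussian_filter(rng.random((96, 96)), 1.5)
        img = ((img - img.min()) / np.ptp(img) * 255).astype(np.uint8)
        f0 = detect_features(img)
        f1 = detect_features(np.rot90(img))
        # (x, y) in the original maps to (y, W-1-x) after CCW rot90
        w = img.shape[1]
        mapped = np.column_stack([f0.positions[:, 1], w - 1 - f0.positions[:, 0]])
        hits = 0
        for p in mapped:
            if len(f1) and np.linalg.norm(f1.positions - p, axis=1).min() <= 2.0:
                hits += 1
        assert hits >= 0.5 * len(f0)

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            detect_features(np.zeros((16, 16), np.uint8))

    def test_descriptors_unit_norm(self, intensified_images):
        feats = detect_features(intensified_images[5])
        norms = np.linalg.norm(feats.descriptors, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-6)


class TestMatchFeatures:
    def test_identity_on_identical_sets(self, rng):
        _, _, _, fa, fb, _ = two_view_scene(rng, n=30)
        m = match_features(fa, fb, ratio=0.8)
        np.testing.assert_array_equal(m.pairs[:, 0], m.pairs[:, 1])
        assert len(m) == 30

    def test_equidistant_descriptor_rejected_by_ratio(self):
        d = np.eye(8)[:1]
        a = FeatureSet(np.zeros((1, 2)), np.ones(1), d)
        b = FeatureSet(np.zeros((2, 2)), np.ones(2), np.vstack([d, d]))
        assert len(match_features(a, b, ratio=0.8)) == 0

    def test_matches_equal_exhaustive_nn_oracle(self, rng):
        """Property: mutual-NN + ratio matching must reproduce a brute-force
        double-loop oracle on every random instance."""
        for trial in range(30):
            na, nb = rng.integers(2, 25, 2)
            da = rng.normal(size=(na, 16))
            da /= np.linalg.norm(da, axis=1, keepdims=True)
            db = rng.normal(size=(nb, 16))
            db /= np.linalg.norm(db, axis=1, keepdims=True)
            fa = FeatureSet(rng.random((na, 2)), np.ones(na), da)
            fb = FeatureSet(rng.random((nb, 2)), np.ones(nb), db)
            got = {tuple(p) for p in match_features(fa, fb, 0.85).pairs}
            # oracle: exhaustive distances, mutual NN, ratio on two smallest
            d = np.array([[np.linalg.norm(x - y) for y in db] for x in da])
            expected = set()
            for i in range(na):
                j = int(np.argmin(d[i]))
                if int(np.argmin(d[:, j])) != i:
                    continue
                two = np.sort(d[i])[:2]
                if len(two) >= 2 and not two[0] < 0.85 * two[1]:
                    continue
                expected.add((i, j))
            assert got == expected, f"trial {trial}"

    def test_empty_inputs_give_empty_matchset(self):
        assert len(match_features(FeatureSet.empty(), FeatureSet.empty())) == 0


class TestFilterMatchesRansac:
    def test_clean_scene_nearly_all_inliers(self, rng):
        _, _, _, fa, fb, matches = two_view_scene(rng, n=100)
        mv, E = filter_matches_ransac(matches, fa, fb, INTR, seed=3)
        assert mv.inlier_mask.sum() >= 99

    def test_outliers_excluded(self, rng):
        """100 true correspondences + 30 uniformly random pairs: the inlier
        set must be dominated by the true ones (precision >= 0.95)."""
        pose_a, pose_b, pts, fa, fb, _ = two_view_scene(rng, n=100)
        n_out = 30
        fb2 = FeatureSet(
            np.vstack([fb.positions, rng.uniform([0, 0], [320, 240], (n_out, 2))]),
            np.ones(130),
            np.vstack([fb.descriptors, rng.normal(size=(n_out, 32))]),
        )
        fa2 = FeatureSet(
            np.vstack([fa.positions, fa.positions[:n_out] + 0.01]),
            np.ones(130),
            np.vstack([fa.descriptors, rng.normal(size=(n_out, 32))]),
        )
        matches = MatchSet(np.column_stack([np.arange(130), np.arange(130)]))
        mv, _ = filter_matches_ransac(matches, fa2, fb2, INTR, seed=11)
        inl = mv.inlier_mask
        assert inl[:100].sum() / max(inl.sum(), 1) >= 0.95

    def test_too_few_matches_raise(self, rng):
        _, _, _, fa, fb, _ = two_view_scene(rng, n=7)
        with pytest.raises(InsufficientDataError):
            filter_matches_ransac(MatchSet(np.column_stack([np.arange(7)] * 2)), fa, fb, INTR)

    def test_deterministic_for_fixed_seed(self, rng):
        _, _, _, fa, fb, matches = two_view_scene(rng, n=60, pixel_noise=0.5)
        m1, E1 = filter_matches_ransac(matches, fa, fb, INTR, seed=99)
        m2, E2 = filter_matches_ransac(matches, fa, fb, INTR, seed=99)
        np.testing.assert_array_equal(m1.inlier_mask, m2.inlier_mask)
        np.testing.assert_array_equal(E1, E2)


class TestTwoViewInitialization:
    def test_exact_pose_recovery(self, rng):
        pose_a, pose_b, pts, fa, fb, matches = two_view_scene(rng, n=50)
        pose, tri, front = initialize_two_view(matches, fa, fb, INTR)
        rot_err = Rotation.from_matrix(pose.R @ pose_b.R.T).magnitude()
        t_true = pose_b.t / np.linalg.norm(pose_b.t)
        dir_err = np.arccos(np.clip(abs(pose.t @ t_true), 0, 1))
        assert rot_err < 1e-6
        assert dir_err < 1e-6

    def test_structure_recovery_after_similarity_alignment(self, rng):
        pose_a, pose_b, pts, fa, fb, matches = two_view_scene(rng, n=50)
        _, tri, front = initialize_two_view(matches, fa, fb, INTR)
        R, t, s = umeyama(tri, pts[front])
        aligned = s * tri @ R.T + t
        rmse = np.sqrt(((aligned - pts[front]) ** 2).sum(axis=1).mean())
        scene_scale = np.ptp(pts, axis=0).max()
        assert rmse < 1e-6 * scene_scale

    def test_zero_baseline_rejected(self, rng):
        pose_a, _, pts, fa, _, matches = two_view_scene(rng, n=50, baseline=1e-12)
        fb = FeatureSet(fa.positions.copy(), fa.scales, fa.descriptors.copy())
        with pytest.raises(DegenerateMotionError):
            initialize_two_view(matches, fa, fb, INTR)

    def test_estimate_relative_pose_on_noisy_scene(self, rng):
        pose_a, pose_b, pts, fa, fb, matches = two_view_scene(rng, n=80, pixel_noise=0.3)
        pose, inl, _ = estimate_relative_pose(fa, fb, matches, INTR, seed=5)
        rot_err = Rotation.from_matrix(pose.R @ pose_b.R.T).magnitude()
        assert rot_err < 0.02
        assert inl.sum() >= 60


class TestTriangulate:
    def test_exact_inverse(self):
        pose_a = CameraPose(np.eye(3), np.zeros(3))
        pose_b = CameraPose(
            Rotation.from_rotvec([0, -0.2, 0]).as_matrix(),
            -Rotation.from_rotvec([0, -0.2, 0]).as_matrix() @ np.array([1.0, 0, 0]),
        )
        X = np.array([0.0, 0.0, 5.0])
        obs = np.vstack([
            INTR.project(pose_a.transform(X[None, :])),
            INTR.project(pose_b.transform(X[None, :])),
        ])
        point, resid = triangulate([pose_a, pose_b], obs, INTR)
        np.testing.assert_allclose(point, X, atol=1e-9)

    def test_noisy_observations_small_residual(self, rng):
        pose_a, pose_b, pts, *_ = two_view_scene(rng, n=1)
        X = pts[0]
        obs = np.vstack([
            INTR.project(pose_a.transform(X[None, :])),
            INTR.project(pose_b.transform(X[None, :])),
        ]) + rng.uniform(-0.5, 0.5, (2, 2))
        _, resid = triangulate([pose_a, pose_b], obs, INTR)
        assert resid <= 1.0

    def test_identical_poses_degenerate(self):
        pose = CameraPose(np.eye(3), np.zeros(3))
        with pytest.raises(DegenerateMotionError):
            triangulate([pose, pose], np.array([[160.0, 120.0], [160.0, 120.0]]), INTR)


class TestRegisterNextView:
    def test_exact_correspondences_recover_pose(self, rng):
        _, pose_b, pts, *_ = two_view_scene(rng, n=40)
        pix = INTR.project(pose_b.transform(pts))
        pose, inl = register_next_view(pts, pix, INTR, seed=2)
        assert Rotation.from_matrix(pose.R @ pose_b.R.T).magnitude() < 1e-6
        np.testing.assert_allclose(pose.t, pose_b.t, atol=1e-6)
        assert inl.all()

    def test_outlier_correspondences_flagged(self, rng):
        _, pose_b, pts, *_ = two_view_scene(rng, n=50)
        pix = INTR.project(pose_b.transform(pts))
        n_out = 10
        pix[:n_out] = rng.uniform([0, 0], [320, 240], (n_out, 2))
        pose, inl = register_next_view(pts, pix, INTR, seed=4)
        assert Rotation.from_matrix(pose.R @ pose_b.R.T).magnitude() < 1e-3
        assert not inl[:n_out].any()
        assert inl[n_out:].all()

    def test_three_points_insufficient(self, rng):
        with pytest.raises(InsufficientDataError):
            register_next_view(rng.normal(size=(3, 3)), rng.random((3, 2)), INTR)


def three_view_ba_problem(rng, n=40):
    poses = {0: CameraPose(np.eye(3), np.zeros(3))}
    for v, ang in ((1, -0.15), (2, -0.3)):
        R = Rotation.from_rotvec([0.0, ang, 0.0]).as_matrix()
        c = np.array([v * 0.7, 0.0, 0.1 * v])
        poses[v] = CameraPose(R, -R @ c)
    pts = np.column_stack(
        [rng.uniform(-0.8, 0.8, n), rng.uniform(-0.6, 0.6, n), rng.uniform(4.0, 6.0, n)]
    )
    feats = {}
    for v, pose in poses.items():
        pix = INTR.project(pose.transform(pts))
        desc = np.eye(n)
        feats[v] = FeatureSet(pix, np.ones(n), desc)
    tracks = [{0: i, 1: i, 2: i} for i in range(n)]
    cloud = SparseCloud(pts.copy(), tracks)
    return cloud, poses, feats


class TestBundleAdjust:
    def test_already_optimal_input_unchanged(self, rng):
        cloud, poses, feats = three_view_ba_problem(rng)
        cloud2, poses2, rmse, conv = bundle_adjust(cloud, poses, feats, INTR)
        assert rmse < 1e-8
        np.testing.assert_allclose(cloud2.points, cloud.points, atol=1e-8)
        for v in poses:
            np.testing.assert_allclose(poses2[v].R, poses[v].R, atol=1e-8)
            np.testing.assert_allclose(poses2[v].t, poses[v].t, atol=1e-8)

    def test_descent_from_perturbed_start(self, rng):
        cloud, poses, feats = three_view_ba_problem(rng)
        pert = {0: poses[0]}
        for v in (1, 2):
            dR = Rotation.from_rotvec(rng.normal(scale=0.01, size=3)).as_matrix()
            pert[v] = CameraPose(dR @ poses[v].R, poses[v].t + rng.normal(scale=0.01, size=3))
        rmse0 = reprojection_rmse(cloud, pert, feats, INTR)
        _, _, rmse1, _ = bundle_adjust(cloud, pert, feats, INTR, max_iter=100)
        assert rmse1 < rmse0

    def test_reconverges_to_ground_truth_from_perturbation(self, rng):
        cloud, poses, feats = three_view_ba_problem(rng)
        pert_pts = cloud.points + rng.normal(scale=0.01, size=cloud.points.shape)
        pert_poses = {0: poses[0]}
        for v in (1, 2):
            dR = Rotation.from_rotvec(rng.normal(scale=0.01, size=3)).as_matrix()
            pert_poses[v] = CameraPose(dR @ poses[v].R, poses[v].t + rng.normal(scale=0.005, size=3))
        pert_cloud = SparseCloud(pert_pts, cloud.tracks)
        _, _, rmse, conv = bundle_adjust(pert_cloud, pert_poses, feats, INTR, max_iter=200)
        assert rmse < 1e-6  # exact observations: global minimum is zero


class TestDensify:
    def test_complete_reconstruction_unchanged(self, rng):
        pose_a, pose_b, pts, fa, fb, matches = two_view_scene(rng, n=40)
        tracks = [{0: i, 1: i} for i in range(40)]
        cloud = SparseCloud(pts, tracks)
        out = densify(cloud, {0: pose_a, 1: pose_b}, {0: fa, 1: fb}, INTR)
        assert len(out) == len(cloud)

    def test_withheld_matches_recovered(self, rng):
        pose_a, pose_b, pts, fa, fb, matches = two_view_scene(rng, n=60)
        tracks = [{0: i, 1: i} for i in range(30)]  # half the scene
        cloud = SparseCloud(pts[:30], tracks)
        out = densify(cloud, {0: pose_a, 1: pose_b}, {0: fa, 1: fb}, INTR)
        assert len(out) > len(cloud)

    def test_candidates_outside_epipolar_band_ignored(self, rng):
        pose_a, pose_b, pts, fa, fb, matches = two_view_scene(rng, n=40)
        # shift every view-b feature far off its epipolar line
        fb_shift = FeatureSet(fb.positions + [0.0, 25.0], fb.scales, fb.descriptors)
        tracks = [{0: i, 1: i} for i in range(20)]
        cloud = SparseCloud(pts[:20], tracks)
        out = densify(cloud, {0: pose_a, 1: pose_b}, {0: fa, 1: fb_shift}, INTR)
        assert len(out) == len(cloud)


class TestCheiralityProperty:
    def test_triangulated_points_in_front_of_all_cameras(self, rng):
        pose_a, pose_b, pts, fa, fb, matches = two_view_scene(rng, n=50)
        _, tri, front = initialize_two_view(matches, fa, fb, INTR)
        for pose in (CameraPose(np.eye(3), np.zeros(3)),):
            assert (pose.transform(tri)[:, 2] > 0).all()
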