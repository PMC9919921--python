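"""Incremental structure-from-motion on intensified thermal frames.

The pipeline follows the classical incremental recipe: exhaustive pairwise
descriptor matching ("compute missing matches"), essential-matrix RANSAC
verification, two-view initialization on the best-conditioned pair,
incremental pose registration (PnP) with periodic bundle adjustment, and a
final constrained re-matching pass ("find more points") that densifies the
cloud.  The reconstruction is defined up to a 7-DOF similarity gauge: the
first camera is held at the identity and the initial baseline has unit norm;
metric scale is recovered downstream by landmark registration.

All geometric estimation works in undistorted normalized camera coordinates;
thresholds are quoted in pixels and converted with the mean focal length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.sparse import lil_matrix
from scipy.spatial.transform import Rotation

from .camera import CameraIntrinsics, CameraPose
from .features import FeatureSet, MatchSet, match_features

logger = logging.getLogger(__name__)

__all__ = [
    "SparseCloud",
    "SfmConfig",
    "InsufficientDataError",
    "DegenerateMotionError",
    "ReconstructionError",
    "eight_point_essential",
    "sampson_distance",
    "filter_matches_ransac",
    "initialize_two_view",
    "estimate_relative_pose",
    "homography_ransac",
    "decompose_homography",
    "triangulate",
    "register_next_view",
    "bundle_adjust",
    "densify",
    "reconstruct",
]


class InsufficientDataError(ValueError):
    pass


class DegenerateMotionError(ValueError):
    pass


class ReconstructionError(RuntimeError):
    pass


@dataclass
class SparseCloud:
    """3D points with their image tracks.

    ``tracks[i]`` maps view id -> feature index for point i; every track is
    observed in at least two views.
    """

    points: np.ndarray  # (N, 3)
    tracks: list[dict[int, int]]
    values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float)).reshape(-1, 3)
        if len(self.tracks) != len(self.points):
            raise ValueError("points/tracks length mismatch")
        for tr in self.tracks:
            if len(tr) < 2:
                raise ValueError("every track must be observed in >= 2 views")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class SfmConfig:
    """Tunable knobs of the incremental reconstruction driver."""

    ratio: float = 0.9
    ransac_threshold_px: float = 2.5
    ransac_max_iters: int = 5000
    pnp_threshold_px: float = 3.0
    min_init_angle_deg: float = 2.0
    min_triangulation_angle_deg: float = 0.5
    max_features: int | None = 4000
    ba_every: int = 3
    min_pair_inliers: int = 12
    pair_window: int = 3
    distant_pair_min_ratio: float = 0.45
    max_reprojection_px: float = 4.0
    densify_ratio: float = 0.9
    epipolar_band_px: float = 3.0
    final_ba_max_iter: int = 100
    max_cycle_error_rad: float = 0.15
    target_rmse_px: float = 1.1
    max_attempts: int = 1


def _adaptive_iters(inlier_ratio: float, sample_size: int, max_iters: int, confidence: float = 0.999) -> int:
    """RANSAC iteration count for the given confidence; clamped to max_iters."""
    w = min(max(inlier_ratio, 0.0), 0.9999)
    p_good = w**sample_size
    if p_good < 1e-12:
        return max_iters
    return min(max_iters, int(np.ceil(np.log(1 - confidence) / np.log1p(-p_good))) + 1)


# ---------------------------------------------------------------------------
# epipolar geometry


def _normalize_2d(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hartley normalization: zero-mean, mean distance sqrt(2)."""
    mu = x.mean(axis=0)
    d = np.sqrt(((x - mu) ** 2).sum(axis=1)).mean()
    s = np.sqrt(2.0) / max(d, 1e-12)
    T = np.array([[s, 0, -s * mu[0]], [0, s, -s * mu[1]], [0, 0, 1.0]])
    xn = (x - mu) * s
    return T, xn


def eight_point_essential(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Essential matrix from >= 8 normalized-coordinate correspondences.

    Linear 8-point estimate with Hartley conditioning, projected onto the
    essential manifold (singular values 1, 1, 0).  Satisfies x2ᵀ E x1 = 0.
    """
    x1 = np.atleast_2d(x1)
    x2 = np.atleast_2d(x2)
    if len(x1) < 8:
        raise InsufficientDataError("eight-point solver needs >= 8 correspondences")
    T1, a = _normalize_2d(x1)
    T2, b = _normalize_2d(x2)
    A = np.column_stack(
        [
            b[:, 0] * a[:, 0], b[:, 0] * a[:, 1], b[:, 0],
            b[:, 1] * a[:, 0], b[:, 1] * a[:, 1], b[:, 1],
            a[:, 0], a[:, 1], np.ones(len(a)),
        ]
    )
    _, _, Vt = np.linalg.svd(A)
    F = Vt[-1].reshape(3, 3)
    F = T2.T @ F @ T1
    U, _, Vt = np.linalg.svd(F)
    E = U @ np.diag([1.0, 1.0, 0.0]) @ Vt
    return E / np.linalg.norm(E)


def sampson_distance(E: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """First-order geometric (Sampson) distance in normalized coordinates."""
    x1h = np.column_stack([x1, np.ones(len(x1))])
    x2h = np.column_stack([x2, np.ones(len(x2))])
    Ex1 = x1h @ E.T
    Etx2 = x2h @ E
    num = np.einsum("ij,ij->i", x2h, Ex1) ** 2
    den = Ex1[:, 0] ** 2 + Ex1[:, 1] ** 2 + Etx2[:, 0] ** 2 + Etx2[:, 1] ** 2
    return np.sqrt(num / np.maximum(den, 1e-300))



def _pose_plausible(
    E: np.ndarray, x1: np.ndarray, x2: np.ndarray, min_angle_deg: float
) -> bool:
    """Check that an essential matrix admits a non-degenerate motion.

    Near-planar scenes let the linear solver drift toward spurious models
    whose best decomposition has points behind the cameras or essentially
    zero parallax; those models must not win the consensus vote.
    """
    U, _, Vt = np.linalg.svd(E)
    if np.linalg.det(U) < 0:
        U = -U
    if np.linalg.det(Vt) < 0:
        Vt = -Vt
    W = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    pose_a = CameraPose(np.eye(3), np.zeros(3))
    best_front, best_angle = 0, 0.0
    for R in (U @ W @ Vt, U @ W.T @ Vt):
        for tsign in (U[:, 2], -U[:, 2]):
            pose_b = CameraPose(R, tsign)
            pts = _triangulate_pair(pose_a, pose_b, x1, x2)
            ok = np.isfinite(pts).all(axis=1)
            front = ok & (_depths(pose_a, pts) > 0) & (_depths(pose_b, pts) > 0)
            nf = int(front.sum())
            if nf > best_front:
                best_front = nf
                best_angle = float(
                    np.median(triangulation_angles(pose_a, pose_b, pts[front]))
                )
    return best_front >= max(5, int(0.5 * len(x1))) and best_angle >= min_angle_deg

def filter_matches_ransac(
    matches: MatchSet,
    feats_a: FeatureSet,
    feats_b: FeatureSet,
    intrinsics: CameraIntrinsics,
    threshold_px: float = 1.5,
    seed: int = 0,
    max_iters: int = 2000,
    min_angle_deg: float = 0.0,
) -> tuple[MatchSet, np.ndarray]:
    """Essential-matrix RANSAC over putative matches.

    Inliers have Sampson distance (converted to pixels with the mean focal
    length) below ``threshold_px``; the model is re-estimated on the final
    inlier set.  Deterministic for a fixed seed.  Returns the match set with
    its inlier mask filled, plus the essential matrix.
    """
    if len(matches) < 8:
        raise InsufficientDataError(f"RANSAC needs >= 8 matches, got {len(matches)}")
    rng = np.random.default_rng(seed)
    pa = feats_a.positions[matches.pairs[:, 0]]
    pb = feats_b.positions[matches.pairs[:, 1]]
    x1 = intrinsics.pixel_to_normalized(pa)
    x2 = intrinsics.pixel_to_normalized(pb)
    f_mean = 0.5 * (intrinsics.fx + intrinsics.fy)
    thr = threshold_px / f_mean

    n = len(matches)
    best_mask = np.zeros(n, dtype=bool)
    best_E = None
    best_score = -1.0
    it = 0
    needed = max_iters
    while it < min(needed, max_iters):
        it += 1
        sel = rng.choice(n, size=8, replace=False)
        try:
            E = eight_point_essential(x1[sel], x2[sel])
        except np.linalg.LinAlgError:  # pragma: no cover
            continue
        d = sampson_distance(E, x1, x2)
        mask = d < thr
        score = int(mask.sum()) - float(d[mask].sum()) / max(thr * n, 1e-12)
        if score > best_score:
            # local optimization: refit on the consensus set and rescore
            if mask.sum() >= 8:
                try:
                    E2 = eight_point_essential(x1[mask], x2[mask])
                    d2 = sampson_distance(E2, x1, x2)
                    mask2 = d2 < thr
                    score2 = int(mask2.sum()) - float(d2[mask2].sum()) / max(thr * n, 1e-12)
                    if score2 > score and (
                        min_angle_deg <= 0
                        or _pose_plausible(E2, x1[mask2][:40], x2[mask2][:40], min_angle_deg)
                    ):
                        E, mask, score = E2, mask2, score2
                except np.linalg.LinAlgError:  # pragma: no cover
                    pass
            if min_angle_deg > 0 and not _pose_plausible(
                E, x1[mask][:40], x2[mask][:40], min_angle_deg
            ):
                continue
            best_score, best_mask, best_E = score, mask, E
            needed = _adaptive_iters(mask.mean(), 8, max_iters)
    if best_E is None or best_mask.sum() < 8:
        raise DegenerateMotionError("RANSAC failed to find a consistent essential matrix")
    E = eight_point_essential(x1[best_mask], x2[best_mask])
    final_mask = sampson_distance(E, x1, x2) < thr
    if final_mask.sum() < 8 or (
        min_angle_deg > 0
        and not _pose_plausible(E, x1[final_mask][:40], x2[final_mask][:40], min_angle_deg)
    ):
        final_mask = best_mask
        E = best_E
    return MatchSet(matches.pairs, final_mask), E


def guided_match(
    feats_a: FeatureSet,
    feats_b: FeatureSet,
    E: np.ndarray,
    intrinsics: CameraIntrinsics,
    band_px: float = 2.0,
    ratio: float = 0.9,
) -> MatchSet:
    """Epipolar-guided matching: mutual nearest neighbors restricted to the
    epipolar band of a known essential matrix.

    Once a pair's geometry is verified, the ratio test only needs to resolve
    ambiguity *along* the epipolar line, so far more correct correspondences
    survive than in unconstrained matching.
    """
    if len(feats_a) == 0 or len(feats_b) == 0:
        return MatchSet(np.empty((0, 2), dtype=int))
    from scipy.spatial.distance import cdist

    x1 = intrinsics.pixel_to_normalized(feats_a.positions)
    x2 = intrinsics.pixel_to_normalized(feats_b.positions)
    f_mean = 0.5 * (intrinsics.fx + intrinsics.fy)
    x1h = np.column_stack([x1, np.ones(len(x1))])
    x2h = np.column_stack([x2, np.ones(len(x2))])
    Ex1 = x1h @ E.T  # (Na, 3)
    Etx2 = x2h @ E  # (Nb, 3)
    num = (x2h @ Ex1.T) ** 2  # (Nb, Na)
    den = (Ex1[:, 0] ** 2 + Ex1[:, 1] ** 2)[None, :] + (Etx2[:, 0] ** 2 + Etx2[:, 1] ** 2)[:, None]
    samp = np.sqrt(num / np.maximum(den, 1e-300)) * f_mean  # px, (Nb, Na)
    in_band = (samp < band_px).T  # (Na, Nb)
    d = cdist(feats_a.descriptors, feats_b.descriptors)
    d = np.where(in_band, d, np.inf)
    finite_a = np.isfinite(d).any(axis=1)
    if not finite_a.any():
        return MatchSet(np.empty((0, 2), dtype=int))
    nn_ab = np.argmin(d, axis=1)
    nn_ba = np.argmin(d, axis=0)
    i_idx = np.arange(len(feats_a))
    good = finite_a & (nn_ba[nn_ab] == i_idx)
    if d.shape[1] >= 2:
        two = np.partition(d, 1, axis=1)[:, :2]
        with np.errstate(invalid="ignore"):
            good &= np.where(
                np.isfinite(two[:, 1]), two[:, 0] < ratio * two[:, 1], np.isfinite(two[:, 0])
            )
    return MatchSet(np.column_stack([i_idx[good], nn_ab[good]]))


# ---------------------------------------------------------------------------
# triangulation and two-view initialization


def _triangulate_pair(
    pose1: CameraPose, pose2: CameraPose, xn1: np.ndarray, xn2: np.ndarray
) -> np.ndarray:
    """Vectorized two-view linear (DLT) triangulation in normalized coords."""
    P1 = np.hstack([pose1.R, pose1.t[:, None]])
    P2 = np.hstack([pose2.R, pose2.t[:, None]])
    n = len(xn1)
    A = np.empty((n, 4, 4))
    A[:, 0] = xn1[:, 0, None] * P1[2] - P1[0]
    A[:, 1] = xn1[:, 1, None] * P1[2] - P1[1]
    A[:, 2] = xn2[:, 0, None] * P2[2] - P2[0]
    A[:, 3] = xn2[:, 1, None] * P2[2] - P2[1]
    _, _, Vt = np.linalg.svd(A)
    X = Vt[:, -1, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        return X[:, :3] / X[:, 3, None]


def _depths(pose: CameraPose, points: np.ndarray) -> np.ndarray:
    return pose.transform(points)[:, 2]


def triangulation_angles(
    pose1: CameraPose, pose2: CameraPose, points: np.ndarray
) -> np.ndarray:
    """Angle (deg) subtended at each point by the two camera centers."""
    c1, c2 = pose1.center, pose2.center
    v1 = c1 - points
    v2 = c2 - points
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    cosang = np.einsum("ij,ij->i", v1, v2) / np.maximum(n1 * n2, 1e-300)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def triangulate(
    poses: list[CameraPose],
    observations_px: np.ndarray,
    intrinsics: CameraIntrinsics,
    refine: bool = True,
) -> tuple[np.ndarray, float]:
    """Triangulate one 3D point from >= 2 views.

    Linear multi-view DLT followed by a Gauss-Newton refinement of the pixel
    reprojection error.  Returns (point, mean reprojection residual in px).
    Raises :class:`DegenerateMotionError` if the viewing rays are parallel
    (e.g. identical poses).
    """
    obs = np.atleast_2d(observations_px)
    if len(poses) < 2 or len(obs) != len(poses):
        raise InsufficientDataError("need one observation per pose and >= 2 poses")
    xn = intrinsics.pixel_to_normalized(obs)
    rows = []
    for pose, x in zip(poses, xn):
        P = np.hstack([pose.R, pose.t[:, None]])
        rows.append(x[0] * P[2] - P[0])
        rows.append(x[1] * P[2] - P[1])
    A = np.array(rows)
    _, sv, Vt = np.linalg.svd(A)
    if sv[-2] < 1e-10 * max(sv[0], 1e-300):
        raise DegenerateMotionError("parallel viewing rays: triangulation is degenerate")
    X = Vt[-1]
    if abs(X[3]) < 1e-12 * max(np.abs(X[:3]).max(), 1e-300):
        raise DegenerateMotionError("parallel viewing rays: triangulation is degenerate")
    point = X[:3] / X[3]
    if not np.all(np.isfinite(point)):
        raise DegenerateMotionError("parallel viewing rays: triangulation is degenerate")
    ang = triangulation_angles(poses[0], poses[-1], point[None, :])[0]
    if not np.isfinite(ang) or ang < 1e-6:
        raise DegenerateMotionError("parallel viewing rays: triangulation is degenerate")

    def residual(p):
        return np.concatenate(
            [intrinsics.project(pose.transform(p[None, :]))[0] - o for pose, o in zip(poses, obs)]
        )

    if refine:
        sol = least_squares(residual, point, method="lm", max_nfev=50)
        point = sol.x
    res = residual(point).reshape(-1, 2)
    return point, float(np.linalg.norm(res, axis=1).mean())


def initialize_two_view(
    matches: MatchSet,
    feats_a: FeatureSet,
    feats_b: FeatureSet,
    intrinsics: CameraIntrinsics,
    E: np.ndarray | None = None,
    min_angle_deg: float = 0.5,
) -> tuple[CameraPose, np.ndarray, np.ndarray]:
    """Relative pose of view b w.r.t. view a and triangulated points.

    Decomposes the essential matrix into its four (R, t) candidates and keeps
    the one with maximal cheirality (triangulated points in front of both
    cameras); ties break on lower reprojection residual.  The baseline is
    scaled to unit norm (gauge convention).  Returns (pose_b, points, mask of
    inlier matches that produced valid points).
    """
    pairs = matches.inliers
    if len(pairs) < 8:
        raise InsufficientDataError("two-view initialization needs >= 8 verified matches")
    x1 = intrinsics.pixel_to_normalized(feats_a.positions[pairs[:, 0]])
    x2 = intrinsics.pixel_to_normalized(feats_b.positions[pairs[:, 1]])
    if E is None:
        E = eight_point_essential(x1, x2)
    U, _, Vt = np.linalg.svd(E)
    if np.linalg.det(U) < 0:
        U = -U
    if np.linalg.det(Vt) < 0:
        Vt = -Vt
    W = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    pose_a = CameraPose(np.eye(3), np.zeros(3))
    best = None
    for R in (U @ W @ Vt, U @ W.T @ Vt):
        for tsign in (U[:, 2], -U[:, 2]):
            pose_b = CameraPose(R, tsign / np.linalg.norm(tsign))
            pts = _triangulate_pair(pose_a, pose_b, x1, x2)
            ok = np.isfinite(pts).all(axis=1)
            front = ok & (_depths(pose_a, pts) > 0) & (_depths(pose_b, pts) > 0)
            n_front = int(front.sum())
            resid = np.inf
            if n_front:
                proj = intrinsics.project(pose_b.transform(pts[front]))
                resid = float(
                    np.linalg.norm(proj - feats_b.positions[pairs[front, 1]], axis=1).mean()
                )
            cand = (n_front, -resid, pose_b, pts, front)
            if best is None or cand[:2] > best[:2]:
                best = cand
    n_front, _, pose_b, pts, front = best
    if n_front < 8:
        raise DegenerateMotionError("no essential-matrix candidate passes the cheirality test")
    ang = triangulation_angles(pose_a, pose_b, pts[front])
    if np.median(ang) < min_angle_deg:
        raise DegenerateMotionError(
            f"median triangulation angle {np.median(ang):.3f} deg: baseline too small"
        )
    return pose_b, pts[front], front



# ---------------------------------------------------------------------------
# homography-based relative pose (quasi-planar scenes)


def homography_dlt(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Plane-induced homography from >= 4 normalized correspondences."""
    n = len(x1)
    if n < 4:
        raise InsufficientDataError("homography needs >= 4 correspondences")
    A = np.zeros((2 * n, 9))
    x1h = np.column_stack([x1, np.ones(n)])
    A[0::2, 0:3] = -x1h
    A[0::2, 6:9] = x2[:, 0, None] * x1h
    A[1::2, 3:6] = -x1h
    A[1::2, 6:9] = x2[:, 1, None] * x1h
    _, _, Vt = np.linalg.svd(A)
    return Vt[-1].reshape(3, 3)


def _homography_transfer_error(H: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    p = np.column_stack([x1, np.ones(len(x1))]) @ H.T
    with np.errstate(all="ignore"):
        p = p[:, :2] / p[:, 2:3]
    return np.where(np.isfinite(p).all(axis=1), np.linalg.norm(p - x2, axis=1), np.inf)


def homography_ransac(
    x1: np.ndarray, x2: np.ndarray, threshold: float, seed: int = 0, max_iters: int = 1500
) -> tuple[np.ndarray | None, np.ndarray]:
    """4-point RANSAC homography with local refit; threshold in normalized
    units.  Returns (H or None, inlier mask)."""
    rng = np.random.default_rng(seed)
    n = len(x1)
    if n < 4:
        return None, np.zeros(n, dtype=bool)
    best, best_mask = None, np.zeros(n, dtype=bool)
    # the full iteration budget is always spent: on surfaces with several
    # quasi-planar patches an early exit would lock onto the first local
    # patch instead of the dominant consensus
    for _ in range(max_iters):
        sel = rng.choice(n, 4, replace=False)
        try:
            H = homography_dlt(x1[sel], x2[sel])
        except (np.linalg.LinAlgError, InsufficientDataError):  # pragma: no cover
            continue
        mask = _homography_transfer_error(H, x1, x2) < threshold
        if mask.sum() > best_mask.sum():
            if mask.sum() >= 4:
                try:
                    H2 = homography_dlt(x1[mask], x2[mask])
                    m2 = _homography_transfer_error(H2, x1, x2) < threshold
                    if m2.sum() >= mask.sum():
                        H, mask = H2, m2
                except np.linalg.LinAlgError:  # pragma: no cover
                    pass
            best, best_mask = H, mask
    return best, best_mask


def decompose_homography(H: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Decompose a calibrated homography into candidate (R, t) motions.

    SVD-based closed form; returns up to four physically distinct
    candidates (the plane normal is dropped).  A pure-rotation homography
    (no parallax) yields an empty list.
    """
    x1h = np.column_stack([x1, np.ones(len(x1))])
    x2h = np.column_stack([x2, np.ones(len(x2))])
    if np.sign(np.einsum("ij,ij->i", x2h, x1h @ H.T)).sum() < 0:
        H = -H
    _, S, _ = np.linalg.svd(H)
    Hn = H / S[1]
    _, S, Vt = np.linalg.svd(Hn)
    d1, _, d3 = S
    if d1 - d3 < 1e-9:
        return []
    V = Vt.T
    v1, v2, v3 = V[:, 0], V[:, 1], V[:, 2]
    a = np.sqrt(max(1 - d3**2, 0.0))
    b = np.sqrt(max(d1**2 - 1, 0.0))
    c = np.sqrt(d1**2 - d3**2)
    sols = []
    for u in ((a * v1 + b * v3) / c, (a * v1 - b * v3) / c):
        U1 = np.column_stack([v2, u, np.cross(v2, u)])
        W1 = np.column_stack([Hn @ v2, Hn @ u, np.cross(Hn @ v2, Hn @ u)])
        R = W1 @ U1.T
        t = (Hn - R) @ np.cross(v2, u)
        for sgn in (1.0, -1.0):
            sols.append((R, sgn * t))
    return sols


def _essential_candidates(E: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    U, _, Vt = np.linalg.svd(E)
    if np.linalg.det(U) < 0:
        U = -U
    if np.linalg.det(Vt) < 0:
        Vt = -Vt
    W = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    return [
        (R, tsign) for R in (U @ W @ Vt, U @ W.T @ Vt) for tsign in (U[:, 2], -U[:, 2])
    ]


def _score_motion_candidates(
    candidates: list[tuple[np.ndarray, np.ndarray]],
    x1: np.ndarray,
    x2: np.ndarray,
    pa: np.ndarray,
    pb: np.ndarray,
    intrinsics: CameraIntrinsics,
    threshold_px: float,
    min_angle_deg: float,
) -> list[tuple[CameraPose, np.ndarray, int]]:
    """Score raw (R, t) motion candidates by triangulation support.

    Returns the plausible candidates as (unit-baseline pose, inlier mask,
    support count), best first; candidates failing cheirality or the
    parallax requirement are discarded.  Near-duplicate poses are merged.
    """
    pose_a = CameraPose(np.eye(3), np.zeros(3))
    scored: list[tuple[CameraPose, np.ndarray, int]] = []
    for R, t in candidates:
        if abs(np.linalg.det(R) - 1) > 1e-6:
            continue
        tn = np.linalg.norm(t)
        if tn < 1e-9:
            continue
        pose_b = CameraPose(R, t / tn)
        pts = _triangulate_pair(pose_a, pose_b, x1, x2)
        front = (
            np.isfinite(pts).all(axis=1)
            & (_depths(pose_a, pts) > 0)
            & (_depths(pose_b, pts) > 0)
        )
        if front.sum() < 5:
            continue
        ra = np.full(len(pts), np.inf)
        rb = np.full(len(pts), np.inf)
        ra[front] = np.linalg.norm(
            intrinsics.project(pose_a.transform(pts[front])) - pa[front], axis=1
        )
        rb[front] = np.linalg.norm(
            intrinsics.project(pose_b.transform(pts[front])) - pb[front], axis=1
        )
        inl = front & (ra < threshold_px) & (rb < threshold_px)
        if inl.sum() < 8:
            continue
        if np.median(triangulation_angles(pose_a, pose_b, pts[inl])) < min_angle_deg:
            continue
        dup = False
        for prev, _, _ in scored:
            if (
                Rotation.from_matrix(prev.R @ pose_b.R.T).magnitude() < 0.02
                and np.arccos(np.clip(abs(prev.t @ pose_b.t), 0, 1)) < 0.02
            ):
                dup = True
                break
        if not dup:
            scored.append((pose_b, inl, int(inl.sum())))
    scored.sort(key=lambda c: -c[2])
    return scored


def motion_candidates(
    feats_a: FeatureSet,
    feats_b: FeatureSet,
    matches: MatchSet,
    intrinsics: CameraIntrinsics,
    seed: int = 0,
    threshold_px: float = 2.5,
    max_iters: int = 3000,
    min_angle_deg: float = 2.0,
    max_candidates: int = 4,
) -> list[tuple[CameraPose, np.ndarray, int]]:
    """Plausible relative-motion hypotheses for one image pair.

    Pools decompositions from several independent homography-RANSAC runs
    (the stable model for the quasi-planar surfaces of close-range body
    imaging) and essential-matrix RANSAC, scored by triangulation support.
    Several hypotheses may carry similar support on near-planar data (the
    two homography branches); the caller disambiguates them, e.g. by
    rotation cycle consistency across the view graph.
    """
    if len(matches) < 8:
        raise InsufficientDataError("relative pose needs >= 8 matches")
    pa = feats_a.positions[matches.pairs[:, 0]]
    pb = feats_b.positions[matches.pairs[:, 1]]
    x1 = intrinsics.pixel_to_normalized(pa)
    x2 = intrinsics.pixel_to_normalized(pb)
    f_mean = 0.5 * (intrinsics.fx + intrinsics.fy)
    raw: list[tuple[np.ndarray, np.ndarray]] = []
    for k in range(3):
        H, hmask = homography_ransac(
            x1, x2, threshold=threshold_px / f_mean, seed=seed + 31 * k
        )
        if H is not None and hmask.sum() >= 10:
            try:
                Hfit = homography_dlt(x1[hmask], x2[hmask])
                raw += decompose_homography(Hfit, x1[hmask], x2[hmask])
            except np.linalg.LinAlgError:  # pragma: no cover
                pass
    for k in range(2):
        try:
            _, E = filter_matches_ransac(
                matches, feats_a, feats_b, intrinsics,
                threshold_px=threshold_px, seed=seed + 1 + 97 * k, max_iters=max_iters,
            )
            raw += _essential_candidates(E)
        except (InsufficientDataError, DegenerateMotionError):
            continue
    if not raw:
        raise DegenerateMotionError("no motion candidate from homography or essential matrix")
    scored = _score_motion_candidates(
        raw, x1, x2, pa, pb, intrinsics, threshold_px, min_angle_deg
    )
    if not scored:
        raise DegenerateMotionError("no essential-matrix candidate passes the cheirality test")
    return scored[:max_candidates]


def refine_relative_pose(
    pose_b: CameraPose,
    feats_a: FeatureSet,
    feats_b: FeatureSet,
    matches: MatchSet,
    intrinsics: CameraIntrinsics,
    threshold_px: float = 2.5,
) -> tuple[CameraPose, np.ndarray]:
    """Polish a relative-pose hypothesis with a two-view bundle adjustment
    over its triangulated inliers; returns (unit-baseline pose, inliers)."""
    pa = feats_a.positions[matches.pairs[:, 0]]
    pb = feats_b.positions[matches.pairs[:, 1]]
    x1 = intrinsics.pixel_to_normalized(pa)
    x2 = intrinsics.pixel_to_normalized(pb)
    pose_a = CameraPose(np.eye(3), np.zeros(3))

    def inliers_of(pose):
        pts = _triangulate_pair(pose_a, pose, x1, x2)
        front = (
            np.isfinite(pts).all(axis=1)
            & (_depths(pose_a, pts) > 0)
            & (_depths(pose, pts) > 0)
        )
        ra = np.full(len(pts), np.inf)
        rb = np.full(len(pts), np.inf)
        ra[front] = np.linalg.norm(
            intrinsics.project(pose_a.transform(pts[front])) - pa[front], axis=1
        )
        rb[front] = np.linalg.norm(
            intrinsics.project(pose.transform(pts[front])) - pb[front], axis=1
        )
        return front & (ra < threshold_px) & (rb < threshold_px), pts

    inl, pts = inliers_of(pose_b)
    if inl.sum() >= 8:
        sub_tracks = [{0: int(ia), 1: int(ib)} for ia, ib in matches.pairs[inl]]
        cl = SparseCloud(pts[inl], sub_tracks)
        _, ps2, _, _ = bundle_adjust(
            cl, {0: pose_a, 1: pose_b}, {0: feats_a, 1: feats_b}, intrinsics,
            max_iter=150, loss="soft_l1",
        )
        cand = ps2[1]
        nb = np.linalg.norm(cand.t)
        if nb > 1e-9:
            cand = CameraPose(cand.R, cand.t / nb)
            inl2, _ = inliers_of(cand)
            if inl2.sum() >= inl.sum() * 0.8:
                pose_b, inl = cand, inl2
    return pose_b, inl


def estimate_relative_pose(
    feats_a: FeatureSet,
    feats_b: FeatureSet,
    matches: MatchSet,
    intrinsics: CameraIntrinsics,
    seed: int = 0,
    threshold_px: float = 2.5,
    max_iters: int = 3000,
    min_angle_deg: float = 2.0,
    refine: bool = True,
) -> tuple[CameraPose, np.ndarray, np.ndarray]:
    """Robust relative pose of view b w.r.t. view a (unit baseline).

    Takes the best-supported hypothesis from :func:`motion_candidates` and
    polishes it with a two-view bundle adjustment.  Returns (pose_b, inlier
    mask over matches, triangulated points for all matches).
    """
    cands = motion_candidates(
        feats_a, feats_b, matches, intrinsics, seed=seed,
        threshold_px=threshold_px, max_iters=max_iters, min_angle_deg=min_angle_deg,
    )
    pose_b, inl, _ = cands[0]
    if refine:
        pose_b, inl = refine_relative_pose(
            pose_b, feats_a, feats_b, matches, intrinsics, threshold_px=threshold_px
        )
    x1 = intrinsics.pixel_to_normalized(feats_a.positions[matches.pairs[:, 0]])
    x2 = intrinsics.pixel_to_normalized(feats_b.positions[matches.pairs[:, 1]])
    pts = _triangulate_pair(CameraPose(np.eye(3), np.zeros(3)), pose_b, x1, x2)
    return pose_b, inl, pts


# ---------------------------------------------------------------------------
# PnP


def _pose_from_projection(P: np.ndarray) -> CameraPose:
    """Nearest rigid pose to a 3x4 projection matrix estimated up to scale."""
    M = P[:, :3]
    U, s, Vt = np.linalg.svd(M)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = -R
        P = -P
        U, s, Vt = np.linalg.svd(-M)
    scale = s.mean()
    t = P[:, 3] / scale
    return CameraPose(R, t)


def _pnp_dlt(points3d: np.ndarray, xn: np.ndarray) -> CameraPose:
    """Linear pose estimate from >= 6 2D(normalized)-3D correspondences."""
    n = len(points3d)
    A = np.zeros((2 * n, 12))
    Xh = np.hstack([points3d, np.ones((n, 1))])
    A[0::2, 0:4] = Xh
    A[0::2, 8:12] = -xn[:, 0, None] * Xh
    A[1::2, 4:8] = Xh
    A[1::2, 8:12] = -xn[:, 1, None] * Xh
    _, _, Vt = np.linalg.svd(A)
    P = Vt[-1].reshape(3, 4)
    pose = _pose_from_projection(P)
    if np.median(_depths(pose, points3d)) < 0:
        pose = _pose_from_projection(-P)
    return pose


def _refine_pose(
    pose: CameraPose,
    points3d: np.ndarray,
    pix: np.ndarray,
    intrinsics: CameraIntrinsics,
) -> CameraPose:
    rv0 = Rotation.from_matrix(pose.R).as_rotvec()

    def residual(p):
        R = Rotation.from_rotvec(p[:3]).as_matrix()
        cam = points3d @ R.T + p[3:6]
        return (intrinsics.project(cam) - pix).ravel()

    sol = least_squares(residual, np.concatenate([rv0, pose.t]), method="lm", max_nfev=100)
    return CameraPose(Rotation.from_rotvec(sol.x[:3]).as_matrix(), sol.x[3:6])


def register_next_view(
    points3d: np.ndarray,
    pix2d: np.ndarray,
    intrinsics: CameraIntrinsics,
    seed: int = 0,
    threshold_px: float = 2.0,
    max_iters: int = 500,
) -> tuple[CameraPose, np.ndarray]:
    """RANSAC PnP: camera pose from 2D-3D correspondences to existing tracks.

    Returns (pose, inlier mask).  Needs >= 4 correspondences (>= 6 for the
    linear minimal solver; with 4-5 the full set is used directly).
    """
    points3d = np.atleast_2d(points3d)
    pix2d = np.atleast_2d(pix2d)
    n = len(points3d)
    if n < 4:
        raise InsufficientDataError(f"PnP needs >= 4 correspondences, got {n}")
    xn = intrinsics.pixel_to_normalized(pix2d)
    if n < 6:
        pose = _refine_pose(_pnp_dlt_padded(points3d, xn), points3d, pix2d, intrinsics)
        err = np.linalg.norm(intrinsics.project(pose.transform(points3d)) - pix2d, axis=1)
        return pose, err < threshold_px
    rng = np.random.default_rng(seed)
    best_mask = np.zeros(n, dtype=bool)
    best_pose = None
    needed = max_iters
    it = 0
    while it < min(needed, max_iters):
        it += 1
        sel = rng.choice(n, size=6, replace=False)
        try:
            pose = _pnp_dlt(points3d[sel], xn[sel])
        except (np.linalg.LinAlgError, ValueError):
            continue
        err = np.linalg.norm(intrinsics.project(pose.transform(points3d)) - pix2d, axis=1)
        mask = err < threshold_px
        if mask.sum() > best_mask.sum():
            best_mask, best_pose = mask, pose
            needed = _adaptive_iters(mask.mean(), 6, max_iters)
    if best_pose is None or best_mask.sum() < 4:
        raise InsufficientDataError("PnP RANSAC found no consistent pose")
    pose = _refine_pose(best_pose, points3d[best_mask], pix2d[best_mask], intrinsics)
    err = np.linalg.norm(intrinsics.project(pose.transform(points3d)) - pix2d, axis=1)
    return pose, err < threshold_px


def _pnp_dlt_padded(points3d: np.ndarray, xn: np.ndarray) -> CameraPose:
    """Fallback linear pose for 4-5 correspondences: solve the DLT system in
    least-squares sense (may be poorly conditioned; refined afterwards)."""
    n = len(points3d)
    A = np.zeros((2 * n, 12))
    Xh = np.hstack([points3d, np.ones((n, 1))])
    A[0::2, 0:4] = Xh
    A[0::2, 8:12] = -xn[:, 0, None] * Xh
    A[1::2, 4:8] = Xh
    A[1::2, 8:12] = -xn[:, 1, None] * Xh
    _, _, Vt = np.linalg.svd(A)
    P = Vt[-1].reshape(3, 4)
    pose = _pose_from_projection(P)
    if np.median(_depths(pose, points3d)) < 0:
        pose = _pose_from_projection(-P)
    return pose


# ---------------------------------------------------------------------------
# bundle adjustment


def _gather_observations(
    cloud: SparseCloud, features: dict[int, FeatureSet]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten tracks into (point_idx, view_id, pixel xy) arrays."""
    pi, vi, px = [], [], []
    for i, tr in enumerate(cloud.tracks):
        for v, f in tr.items():
            pi.append(i)
            vi.append(v)
            px.append(features[v].positions[f])
    return np.array(pi, dtype=int), np.array(vi, dtype=int), np.array(px, dtype=float)


def reprojection_rmse(
    cloud: SparseCloud,
    poses: dict[int, CameraPose],
    features: dict[int, FeatureSet],
    intrinsics: CameraIntrinsics,
) -> float:
    """Root-mean-square pixel reprojection error over all observations."""
    pi, vi, px = _gather_observations(cloud, features)
    res = []
    for v in np.unique(vi):
        m = vi == v
        proj = intrinsics.project(poses[v].transform(cloud.points[pi[m]]))
        res.append(proj - px[m])
    res = np.vstack(res)
    return float(np.sqrt((res**2).sum(axis=1).mean()))


def bundle_adjust(
    cloud: SparseCloud,
    poses: dict[int, CameraPose],
    features: dict[int, FeatureSet],
    intrinsics: CameraIntrinsics,
    fix_intrinsics: bool = True,
    max_iter: int = 50,
    tol: float = 1e-10,
    loss: str = "linear",
    f_scale: float = 2.0,
) -> tuple[SparseCloud, dict[int, CameraPose], float, bool]:
    """Joint nonlinear refinement of 3D points and camera poses.

    Levenberg-Marquardt-type trust-region minimization of the total squared
    pixel reprojection error with an analytic sparsity pattern; the first
    camera is held fixed (gauge).  The optimizer only accepts cost-decreasing
    steps, so the RMSE is non-increasing across accepted iterations.

    Returns (cloud, poses, final RMSE, converged flag).
    """
    view_ids = sorted(poses)
    fixed_view = view_ids[0]
    free_views = view_ids[1:]
    pi, vi, px = _gather_observations(cloud, features)
    n_pts = len(cloud)
    n_obs = len(pi)
    cam_index = {v: i for i, v in enumerate(free_views)}

    x0 = []
    for v in free_views:
        x0.append(Rotation.from_matrix(poses[v].R).as_rotvec())
        x0.append(poses[v].t)
    x0.append(cloud.points.ravel())
    intr0 = np.array([intrinsics.fx, intrinsics.fy, intrinsics.cx, intrinsics.cy])
    if not fix_intrinsics:
        x0.append(intr0)
    x0 = np.concatenate(x0)
    n_cam_params = 6 * len(free_views)

    def unpack(x):
        cams = {}
        for v in view_ids:
            if v == fixed_view:
                cams[v] = (poses[fixed_view].R, poses[fixed_view].t)
            else:
                k = 6 * cam_index[v]
                cams[v] = (Rotation.from_rotvec(x[k : k + 3]).as_matrix(), x[k + 3 : k + 6])
        pts = x[n_cam_params : n_cam_params + 3 * n_pts].reshape(-1, 3)
        if fix_intrinsics:
            intr = intrinsics
        else:
            fx, fy, cx, cy = x[n_cam_params + 3 * n_pts :]
            intr = replace(intrinsics, fx=fx, fy=fy, cx=cx, cy=cy)
        return cams, pts, intr

    def residual(x):
        cams, pts, intr = unpack(x)
        out = np.empty((n_obs, 2))
        for v in view_ids:
            m = vi == v
            if not m.any():
                continue
            R, t = cams[v]
            out[m] = intr.project(pts[pi[m]] @ R.T + t) - px[m]
        return out.ravel()

    # sparsity: each observation depends on its camera's 6 params + its point's 3
    n_params = len(x0)
    sp = lil_matrix((2 * n_obs, n_params), dtype=np.uint8)
    rows = np.arange(n_obs)
    for d in (0, 1):
        for j in range(3):
            sp[2 * rows + d, n_cam_params + 3 * pi + j] = 1
    free_mask = vi != fixed_view
    ci = np.array([cam_index.get(v, 0) for v in vi])
    for d in (0, 1):
        for j in range(6):
            sp[2 * rows[free_mask] + d, 6 * ci[free_mask] + j] = 1
    if not fix_intrinsics:
        sp[:, n_cam_params + 3 * n_pts :] = 1

    r0 = residual(x0)
    rmse0 = float(np.sqrt((r0**2).mean() * 2))
    sol = least_squares(
        residual,
        x0,
        jac_sparsity=sp,
        method="trf",
        x_scale="jac",
        loss=loss,
        f_scale=f_scale,
        ftol=tol,
        xtol=tol,
        gtol=tol,
        max_nfev=max_iter,
    )
    converged = bool(sol.status > 0 and sol.cost <= 0.5 * (r0 @ r0) + 1e-12)
    if not converged:
        logger.warning("bundle adjustment did not converge (status=%s)", sol.status)
    cams, pts, _ = unpack(sol.x)
    new_poses = {v: CameraPose(*cams[v]) for v in view_ids}
    new_cloud = SparseCloud(pts, cloud.tracks, cloud.values)
    rmse = float(np.sqrt(2 * sol.cost / n_obs))
    logger.info("bundle adjustment: RMSE %.4f -> %.4f px (%d obs)", rmse0, rmse, n_obs)
    return new_cloud, new_poses, rmse, converged


# ---------------------------------------------------------------------------
# densification and the incremental driver


def _essential_from_poses(pose_a: CameraPose, pose_b: CameraPose) -> np.ndarray:
    """E such that x_bᵀ E x_a = 0 for the relative motion a -> b."""
    R = pose_b.R @ pose_a.R.T
    t = pose_b.t - R @ pose_a.t
    tx = np.array([[0, -t[2], t[1]], [t[2], 0, -t[0]], [-t[1], t[0], 0]])
    E = tx @ R
    n = np.linalg.norm(E)
    return E / n if n > 0 else E


def densify(
    cloud: SparseCloud,
    poses: dict[int, CameraPose],
    features: dict[int, FeatureSet],
    intrinsics: CameraIntrinsics,
    relaxed_ratio: float = 0.9,
    epipolar_band_px: float = 2.0,
    max_reprojection_px: float = 3.0,
) -> SparseCloud:
    """Find more points: re-match yet-unmatched features between consecutive
    registered views under a relaxed ratio test, keep pairs consistent with
    the known epipolar geometry, and triangulate them.

    The point count never decreases; no new points is a valid outcome.
    """
    used: dict[int, set[int]] = {v: set() for v in poses}
    for tr in cloud.tracks:
        for v, f in tr.items():
            used[v].add(f)
    f_mean = 0.5 * (intrinsics.fx + intrinsics.fy)
    new_points, new_tracks = [], []
    view_ids = sorted(poses)
    for a, b in zip(view_ids[:-1], view_ids[1:]):
        free_a = np.array(sorted(set(range(len(features[a]))) - used[a]), dtype=int)
        free_b = np.array(sorted(set(range(len(features[b]))) - used[b]), dtype=int)
        if len(free_a) == 0 or len(free_b) == 0:
            continue
        sub_a = FeatureSet(
            features[a].positions[free_a], features[a].scales[free_a],
            features[a].descriptors[free_a],
        )
        sub_b = FeatureSet(
            features[b].positions[free_b], features[b].scales[free_b],
            features[b].descriptors[free_b],
        )
        m = match_features(sub_a, sub_b, ratio=relaxed_ratio)
        if len(m) == 0:
            continue
        x1 = intrinsics.pixel_to_normalized(sub_a.positions[m.pairs[:, 0]])
        x2 = intrinsics.pixel_to_normalized(sub_b.positions[m.pairs[:, 1]])
        E = _essential_from_poses(poses[a], poses[b])
        keep = sampson_distance(E, x1, x2) * f_mean < epipolar_band_px
        if not keep.any():
            continue
        pts = _triangulate_pair(poses[a], poses[b], x1[keep], x2[keep])
        ok = np.isfinite(pts).all(axis=1)
        ok &= (_depths(poses[a], pts) > 0) & (_depths(poses[b], pts) > 0)
        proj_a = intrinsics.project(poses[a].transform(pts)) - sub_a.positions[m.pairs[keep, 0]]
        proj_b = intrinsics.project(poses[b].transform(pts)) - sub_b.positions[m.pairs[keep, 1]]
        ok &= np.linalg.norm(proj_a, axis=1) < max_reprojection_px
        ok &= np.linalg.norm(proj_b, axis=1) < max_reprojection_px
        for idx in np.nonzero(ok)[0]:
            ia = free_a[m.pairs[keep][idx, 0]]
            ib = free_b[m.pairs[keep][idx, 1]]
            if ia in used[a] or ib in used[b]:
                continue
            used[a].add(ia)
            used[b].add(ib)
            new_points.append(pts[idx])
            new_tracks.append({a: int(ia), b: int(ib)})
    if not new_points:
        return cloud
    logger.info("densify: added %d points (%d -> %d)", len(new_points), len(cloud), len(cloud) + len(new_points))
    return SparseCloud(
        np.vstack([cloud.points, np.array(new_points)]),
        cloud.tracks + new_tracks,
        None,
    )


def _build_tracks(
    verified: dict[tuple[int, int], np.ndarray], n_views: int
) -> list[dict[int, int]]:
    """Merge pairwise matches into multi-view tracks.

    Conflict-avoiding greedy union: two partial tracks are merged only if
    they observe disjoint view sets, so a single wrong match cannot poison
    or destroy otherwise consistent tracks.  Links from closer view pairs
    (more reliable matching) are applied first.
    """
    comp: dict[tuple[int, int], int] = {}  # node -> component id
    members: dict[int, dict[int, int]] = {}  # component id -> {view: feat}
    next_id = 0
    for (a, b), pairs in sorted(verified.items(), key=lambda kv: abs(kv[0][0] - kv[0][1])):
        for ia, ib in pairs:
            na, nb = (a, int(ia)), (b, int(ib))
            ca = comp.get(na)
            cb = comp.get(nb)
            if ca is None and cb is None:
                comp[na] = comp[nb] = next_id
                members[next_id] = {a: int(ia), b: int(ib)}
                next_id += 1
            elif ca is None:
                tr = members[cb]
                if a not in tr:
                    tr[a] = int(ia)
                    comp[na] = cb
            elif cb is None:
                tr = members[ca]
                if b not in tr:
                    tr[b] = int(ib)
                    comp[nb] = ca
            elif ca != cb:
                ta, tb = members[ca], members[cb]
                if not (set(ta) & set(tb)):
                    if len(tb) > len(ta):
                        ca, cb, ta, tb = cb, ca, tb, ta
                    ta.update(tb)
                    for v, f in tb.items():
                        comp[(v, f)] = ca
                    del members[cb]
    return [tr for tr in members.values() if len(tr) >= 2]


def _clean_view_graph(
    rel_poses: dict[tuple[int, int], CameraPose],
    verified: dict[tuple[int, int], np.ndarray],
    essentials: dict[tuple[int, int], np.ndarray],
    max_cycle_error_rad: float,
) -> None:
    """Drop pairwise poses that violate rotation cycle consistency.

    Composing the relative rotations around any view triplet must return
    (approximately) the identity; a pair whose triplets consistently fail
    this is a wrong estimate and would poison chain registration.  Pairs are
    removed worst-first, never disconnecting the view graph.
    """
    from itertools import combinations

    def cycle_medians() -> dict[tuple[int, int], float]:
        errs: dict[tuple[int, int], list[float]] = {q: [] for q in rel_poses}
        views = sorted({v for q in rel_poses for v in q})
        for i, j, k in combinations(views, 3):
            trip = [(i, j), (j, k), (i, k)]
            if not all(q in rel_poses for q in trip):
                continue
            Rc = rel_poses[(j, k)].R @ rel_poses[(i, j)].R @ rel_poses[(i, k)].R.T
            e = float(Rotation.from_matrix(Rc).magnitude())
            for q in trip:
                errs[q].append(e)
        return {q: float(np.median(v)) for q, v in errs.items() if len(v) >= 2}

    def still_connected_without(drop: tuple[int, int]) -> bool:
        keep = [q for q in rel_poses if q != drop]
        parent: dict[int, int] = {}

        def find(x):
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in keep:
            parent[find(a)] = find(b)
        return find(drop[0]) == find(drop[1]) if parent else False

    while True:
        med = cycle_medians()
        if not med:
            return
        worst = max(med, key=med.get)
        if med[worst] <= max_cycle_error_rad:
            return
        if not still_connected_without(worst):
            return
        logger.info(
            "view-graph cleaning: dropping pair %s (median cycle error %.3f rad)",
            worst, med[worst],
        )
        del rel_poses[worst]
        del verified[worst]
        del essentials[worst]


def reconstruct(
    features: dict[int, FeatureSet],
    intrinsics: CameraIntrinsics,
    config: SfmConfig | None = None,
    seed: int = 0,
    init_skip: int = 0,
) -> tuple[SparseCloud, dict[int, CameraPose]]:
    """Full incremental reconstruction driver.

    Takes per-view feature sets (use :func:`thermofuse.features.detect_features`
    on intensified frames), matches all pairs, initializes on the verified
    pair with the most inliers and an adequate baseline, then incrementally
    registers the remaining views with periodic bundle adjustment, finishing
    with a final adjustment and a densification pass.

    The sampling-dependent stages (RANSAC) occasionally steer the whole
    solve into a poor optimum; attempts whose final reprojection RMSE stays
    above ``config.target_rmse_px`` are retried with a shifted RNG stream
    (up to ``config.max_attempts``) and the best attempt is returned.
    """
    config = config or SfmConfig()
    best = None
    last_error: Exception | None = None
    for attempt in range(config.max_attempts):
        try:
            cloud, poses, rmse, n_obs3 = _reconstruct_once(
                features, intrinsics, config, seed + 1000003 * attempt,
                init_skip=init_skip + attempt,
            )
        except (ReconstructionError, InsufficientDataError) as exc:
            last_error = exc
            continue
        # a well-converged solve is rich in long (>= 3-view) tracks: cross-
        # pair correspondences only merge when the poses agree, so this
        # count is a structural quality signal independent of the residual
        quality = (len(poses), n_obs3, -rmse)
        if best is None or quality > best[0]:
            best = (quality, cloud, poses, rmse)
        if rmse <= config.target_rmse_px and len(poses) >= 0.8 * len(features):
            break
        logger.info(
            "attempt %d: rmse %.3f px, %d multi-view obs, %d/%d views; retrying",
            attempt, rmse, n_obs3, len(poses), len(features),
        )
    if best is None:
        raise last_error or ReconstructionError("reconstruction failed")
    _, cloud, poses, rmse = best
    logger.info("reconstruction accepted: %d points, %d views, rmse %.3f px", len(cloud), len(poses), rmse)
    return cloud, poses


def _reconstruct_once(
    features: dict[int, FeatureSet],
    intrinsics: CameraIntrinsics,
    config: SfmConfig,
    seed: int,
    init_skip: int = 0,
) -> tuple[SparseCloud, dict[int, CameraPose], float, int]:
    """One full incremental solve; see :func:`reconstruct`.

    ``init_skip`` rotates the initialization-pair preference so retries
    explore structurally different starting scaffolds.
    """
    view_ids = sorted(features)
    if len(view_ids) < 2:
        raise InsufficientDataError("reconstruction needs >= 2 frames")

    # --- compute missing matches: all-pairs matching + motion hypotheses.
    # On quasi-planar surfaces two motion branches often carry comparable
    # support, so each pair keeps several candidates and the branch is
    # chosen afterwards by rotation cycle consistency across the view graph.
    pair_matches: dict[tuple[int, int], MatchSet] = {}
    pair_cands: dict[tuple[int, int], list] = {}
    identity = CameraPose(np.eye(3), np.zeros(3))
    for i, a in enumerate(view_ids):
        for b in view_ids[i + 1 :]:
            m = match_features(features[a], features[b], ratio=config.ratio)
            if len(m) < 8:
                continue
            try:
                cands = motion_candidates(
                    features[a], features[b], m, intrinsics,
                    seed=seed + 7919 * a + 104729 * b,
                    threshold_px=config.ransac_threshold_px,
                    max_iters=config.ransac_max_iters,
                    min_angle_deg=config.min_init_angle_deg,
                )
            except (InsufficientDataError, DegenerateMotionError):
                continue
            n_inl = cands[0][2]
            if n_inl < config.min_pair_inliers:
                continue
            # frames come from a continuous video sweep: distant frame pairs
            # share little surface, so a distant pair must show an unusually
            # clean consensus before it is trusted
            if abs(a - b) > config.pair_window and n_inl < config.distant_pair_min_ratio * len(m):
                continue
            # refine each hypothesis with a two-view bundle adjustment so
            # the branch selection below compares converged poses
            refined = []
            for pose0, _, _ in cands[:3]:
                pose_r, inl_r = refine_relative_pose(
                    pose0, features[a], features[b], m, intrinsics,
                    threshold_px=config.ransac_threshold_px,
                )
                dup = any(
                    Rotation.from_matrix(pr.R @ pose_r.R.T).magnitude() < 0.02
                    for pr, _, _ in refined
                )
                if not dup and inl_r.sum() >= config.min_pair_inliers:
                    refined.append((pose_r, inl_r, int(inl_r.sum())))
            if not refined:
                continue
            refined.sort(key=lambda c: -c[2])
            pair_matches[(a, b)] = m
            pair_cands[(a, b)] = refined

    # branch selection: iterated conditional modes on the triplet cycle cost
    from itertools import combinations

    selection = {q: 0 for q in pair_cands}
    views_present = sorted({v for q in pair_cands for v in q})
    triplets = [
        (i, j, k)
        for i, j, k in combinations(views_present, 3)
        if (i, j) in pair_cands and (j, k) in pair_cands and (i, k) in pair_cands
    ]

    def sel_R(q):
        return pair_cands[q][selection[q]][0].R

    def pair_cost(q) -> float:
        tot, cnt = 0.0, 0
        for (i, j, k) in triplets:
            if q in ((i, j), (j, k), (i, k)):
                Rc = sel_R((j, k)) @ sel_R((i, j)) @ sel_R((i, k)).T
                tot += float(Rotation.from_matrix(Rc).magnitude())
                cnt += 1
        if cnt == 0:  # no triplet evidence: prefer the best-supported branch
            return -1e-3 * pair_cands[q][selection[q]][2]
        return tot / cnt - 1e-4 * pair_cands[q][selection[q]][2]

    for _sweep in range(4):
        changed = False
        for q in sorted(pair_cands):
            best_k, best_c = selection[q], None
            for k in range(len(pair_cands[q])):
                selection[q] = k
                c = pair_cost(q)
                if best_c is None or c < best_c:
                    best_c, best_k = c, k
            if selection[q] != best_k:
                changed = True
            selection[q] = best_k
        if not changed:
            break

    # refine the selected branch of every pair and build the verified sets
    verified: dict[tuple[int, int], np.ndarray] = {}
    essentials: dict[tuple[int, int], np.ndarray] = {}
    rel_poses: dict[tuple[int, int], CameraPose] = {}
    for (a, b), m in pair_matches.items():
        pose_rel, inl, n_inl = pair_cands[(a, b)][selection[(a, b)]]
        E = _essential_from_poses(identity, pose_rel)
        gm = guided_match(
            features[a], features[b], E, intrinsics,
            band_px=config.epipolar_band_px, ratio=config.densify_ratio,
        )
        verified[(a, b)] = gm.pairs if len(gm) >= n_inl else m.pairs[inl]
        essentials[(a, b)] = E
        rel_poses[(a, b)] = pose_rel
    if not verified:
        raise ReconstructionError("no image pair has >= 8 geometrically verified matches")
    logger.info(
        "verified %d pairs; best has %d inliers",
        len(verified), max(len(p) for p in verified.values()),
    )
    _clean_view_graph(rel_poses, verified, essentials, config.max_cycle_error_rad)
    if not verified:
        raise ReconstructionError("view-graph cleaning removed every verified pair")

    tracks = _build_tracks(verified, len(view_ids))
    track_point: dict[int, np.ndarray] = {}  # track index -> 3D
    poses: dict[int, CameraPose] = {}

    # --- two-view initialization on the best verified pair
    init_order = sorted(verified, key=lambda k: -len(verified[k]))
    init_order = init_order[init_skip:] + init_order[:init_skip]
    init_pair = None
    for a, b in init_order:
        pairs = verified[(a, b)]
        pose_b = rel_poses[(a, b)]
        x1 = intrinsics.pixel_to_normalized(features[a].positions[pairs[:, 0]])
        x2 = intrinsics.pixel_to_normalized(features[b].positions[pairs[:, 1]])
        pts = _triangulate_pair(CameraPose(np.eye(3), np.zeros(3)), pose_b, x1, x2)
        front = (
            np.isfinite(pts).all(axis=1)
            & (_depths(CameraPose(np.eye(3), np.zeros(3)), pts) > 0)
            & (_depths(pose_b, pts) > 0)
        )
        if front.sum() < 8:
            continue
        init_pair = (a, b)
        poses[a] = CameraPose(np.eye(3), np.zeros(3))
        poses[b] = pose_b
        feat_to_track = {
            (v, f): ti for ti, tr in enumerate(tracks) for v, f in tr.items()
        }
        for (ia, ib), X in zip(pairs[front], pts[front]):
            ti = feat_to_track.get((a, int(ia)))
            if ti is not None and ti == feat_to_track.get((b, int(ib))):
                track_point[ti] = X
        break
    if init_pair is None:
        raise ReconstructionError("no verified pair admits a stable two-view initialization")
    logger.info("initialized on pair %s with %d points", init_pair, len(track_point))

    feat_to_track = {(v, f): ti for ti, tr in enumerate(tracks) for v, f in tr.items()}

    def current_cloud() -> tuple[SparseCloud, list[int]]:
        idx = [ti for ti in sorted(track_point) if sum(v in poses for v in tracks[ti]) >= 2]
        pts = np.array([track_point[ti] for ti in idx]).reshape(-1, 3)
        trs = [{v: f for v, f in tracks[ti].items() if v in poses} for ti in idx]
        return SparseCloud(pts, trs), idx

    def prune_observations() -> None:
        """Remove observations with gross reprojection error from their
        tracks; drop points left with fewer than two registered views."""
        for ti in list(track_point):
            tr = tracks[ti]
            obs = [(v, f) for v, f in tr.items() if v in poses]
            if len(obs) < 2:
                track_point.pop(ti, None)
                continue
            X = track_point[ti][None, :]
            bad = []
            for v, f in obs:
                cam = poses[v].transform(X)
                err = np.linalg.norm(
                    intrinsics.project(cam)[0] - features[v].positions[f]
                )
                if cam[0, 2] <= 0 or err > config.max_reprojection_px:
                    bad.append((v, f))
            if len(obs) - len(bad) >= 2:
                for v, f in bad:
                    del tr[v]
            else:
                track_point.pop(ti, None)

    def run_ba(max_iter: int, robust: bool = True) -> None:
        cloud, idx = current_cloud()
        if len(cloud) < 8:
            return
        cloud, new_poses, rmse, _ = bundle_adjust(
            cloud, poses, features, intrinsics, max_iter=max_iter,
            loss="soft_l1" if robust else "linear",
        )
        poses.update(new_poses)
        for k, ti in enumerate(idx):
            track_point[ti] = cloud.points[k]
        prune_observations()

    def triangulate_new() -> None:
        for ti, tr in enumerate(tracks):
            if ti in track_point:
                continue
            obs = [(v, f) for v, f in tr.items() if v in poses]
            if len(obs) < 2:
                continue
            # widest-baseline pair of observing cameras
            best_pair, best_d = None, -1.0
            for i in range(len(obs)):
                for j in range(i + 1, len(obs)):
                    d = np.linalg.norm(poses[obs[i][0]].center - poses[obs[j][0]].center)
                    if d > best_d:
                        best_d, best_pair = d, (obs[i], obs[j])
            (va, fa), (vb, fb) = best_pair
            xa = intrinsics.pixel_to_normalized(features[va].positions[fa][None, :])
            xb = intrinsics.pixel_to_normalized(features[vb].positions[fb][None, :])
            X = _triangulate_pair(poses[va], poses[vb], xa, xb)[0]
            if not np.isfinite(X).all():
                continue
            if _depths(poses[va], X[None, :])[0] <= 0 or _depths(poses[vb], X[None, :])[0] <= 0:
                continue
            if triangulation_angles(poses[va], poses[vb], X[None, :])[0] < config.min_triangulation_angle_deg:
                continue
            errs = np.array([
                np.linalg.norm(
                    intrinsics.project(poses[v].transform(X[None, :]))[0]
                    - features[v].positions[f]
                )
                for v, f in obs
            ])
            good = errs < config.max_reprojection_px
            if good.sum() >= 2:
                # drop inconsistent observations, keep the salvageable track
                for (v, f), g in zip(obs, good):
                    if not g:
                        del tr[v]
                track_point[ti] = X

    triangulate_new()
    run_ba(30)

    def register_by_relative_pose(v: int) -> CameraPose | None:
        """Chain registration: refined pairwise relative pose to a registered
        neighbor, baseline scale resolved against existing 3D points on
        common tracks.  Temporally closer pairs are tried first."""
        cands = []
        for (a, b), prs in verified.items():
            if v == a and b in poses:
                cands.append((abs(a - b), -len(prs), a, b))
            elif v == b and a in poses:
                cands.append((abs(a - b), -len(prs), a, b))
        identity = CameraPose(np.eye(3), np.zeros(3))
        for _, _, a, b in sorted(cands):
            u = b if v == a else a
            prs = verified[(a, b)]
            rel = rel_poses[(a, b)]
            x1 = intrinsics.pixel_to_normalized(features[a].positions[prs[:, 0]])
            x2 = intrinsics.pixel_to_normalized(features[b].positions[prs[:, 1]])
            pts_local = _triangulate_pair(identity, rel, x1, x2)
            front = (
                np.isfinite(pts_local).all(axis=1)
                & (_depths(identity, pts_local) > 0)
                & (_depths(rel, pts_local) > 0)
            )
            if front.sum() < 4:
                continue
            # express triangulated points in u's camera frame
            pts_u = rel.transform(pts_local[front]) if u == b else pts_local[front]
            scales = []
            for (ia, ib), X_l in zip(prs[front], pts_u):
                f_u = ib if u == b else ia
                ti = feat_to_track.get((u, int(f_u)))
                if ti is None or ti not in track_point:
                    continue
                X_cam = poses[u].transform(track_point[ti][None, :])[0]
                denom = float(X_l @ X_l)
                if denom <= 0 or X_cam[2] <= 0 or X_l[2] <= 0:
                    continue
                s = float(X_cam @ X_l) / denom
                if s > 0:
                    scales.append(s)
            if len(scales) < 4:
                continue
            scales = np.array(scales)
            s = float(np.median(scales))
            spread = float(np.median(np.abs(scales - s)))
            if spread > 0.25 * s:  # inconsistent depth votes: unreliable pair
                continue
            if u == a:  # rel maps u-frame -> v-frame
                R, tl = rel.R, s * rel.t
            else:  # rel maps v-frame -> u-frame; invert
                R, tl = rel.R.T, -s * (rel.R.T @ rel.t)
            pose_v = CameraPose(R @ poses[u].R, R @ poses[u].t + tl)
            logger.info(
                "registered view %d via relative pose to view %d (%d scale votes)",
                v, u, len(scales),
            )
            return pose_v
        return None

    # --- incremental registration, alternated with pose-guided
    # retriangulation rounds.  Once poses are known, their exact epipolar
    # geometry lets guided matching harvest far more correspondences than
    # blind RANSAC verification, which both densifies the tracks (rigidity
    # against drift) and unlocks views that could not be registered before.

    def rebuild_tracks(band_px: float) -> None:
        nonlocal tracks, feat_to_track, track_point
        reg = sorted(poses)
        merged: dict[tuple[int, int], np.ndarray] = {}
        for i, a in enumerate(reg):
            for b in reg[i + 1 :]:
                E2 = _essential_from_poses(poses[a], poses[b])
                gm = guided_match(
                    features[a], features[b], E2, intrinsics,
                    band_px=band_px, ratio=config.densify_ratio,
                )
                if len(gm) >= 8:
                    merged[(a, b)] = gm.pairs
        # keep original verified matches for pairs touching unregistered
        # views so those views stay connected to the track graph
        for (a, b), prs in verified.items():
            if (a, b) not in merged:
                merged[(a, b)] = prs
        tracks = _build_tracks(merged, len(view_ids))
        feat_to_track = {(v, f): ti for ti, tr in enumerate(tracks) for v, f in tr.items()}
        track_point = {}
        triangulate_new()
        prune_observations()

    since_ba = 0
    # the epipolar band used to rebuild tracks is annealed: while the poses
    # are still rough a wide band keeps correct correspondences in play, and
    # the final tight band rejects the remaining contamination
    band_schedule = [2.0 * config.epipolar_band_px, 1.33 * config.epipolar_band_px,
                     config.epipolar_band_px]
    for band_px in band_schedule:
        stalled: set[int] = set()
        while True:
            remaining = [v for v in view_ids if v not in poses and v not in stalled]
            if not remaining:
                break
            counts = {
                v: sum(1 for ti in track_point if v in tracks[ti]) for v in remaining
            }
            v = max(counts, key=counts.get)
            corr = [
                (track_point[ti], tracks[ti][v]) for ti in sorted(track_point) if v in tracks[ti]
            ]
            pose = None
            if len(corr) >= 6:
                pts3d = np.array([c[0] for c in corr])
                pix = features[v].positions[[c[1] for c in corr]]
                try:
                    pose, inl = register_next_view(
                        pts3d, pix, intrinsics, seed=seed + 31 * v,
                        threshold_px=config.pnp_threshold_px,
                    )
                    if inl.sum() < max(8, 0.25 * len(corr)):
                        pose = None
                except InsufficientDataError:
                    pose = None
            if pose is None:
                pose = register_by_relative_pose(v)
            if pose is None:
                logger.info("cannot register view %d yet (%d correspondences)", v, len(corr))
                stalled.add(v)
                continue
            stalled.clear()
            poses[v] = pose
            triangulate_new()
            since_ba += 1
            if since_ba >= config.ba_every:
                run_ba(60)
                since_ba = 0
            logger.info(
                "registered view %d (%d 2D-3D correspondences, %d points)",
                v, len(corr), len(track_point),
            )
        run_ba(config.final_ba_max_iter)
        rebuild_tracks(band_px)
        run_ba(config.final_ba_max_iter)

    run_ba(config.final_ba_max_iter, robust=False)
    cloud, _ = current_cloud()
    final_rmse = (
        reprojection_rmse(cloud, poses, features, intrinsics) if len(cloud) else np.inf
    )
    n_obs3 = sum(len(tr) for tr in cloud.tracks if len(tr) >= 3)
    cloud = densify(
        cloud, poses, features, intrinsics,
        relaxed_ratio=config.densify_ratio,
        epipolar_band_px=config.epipolar_band_px,
        max_reprojection_px=config.max_reprojection_px,
    )
    logger.info(
        "reconstruction: %d points, %d views, rmse %.3f px, %d multi-view obs",
        len(cloud), len(poses), final_rmse, n_obs3,
    )
    return cloud, poses, final_rmse, n_obs3


def _reprojection_ok(
    cloud: SparseCloud,
    poses: dict[int, CameraPose],
    features: dict[int, FeatureSet],
    intrinsics: CameraIntrinsics,
    max_px: float,
) -> np.ndarray:
    """Per-point mask: max reprojection error across the track below max_px
    and positive depth in every observing camera."""
    ok = np.ones(len(cloud), dtype=bool)
    pi, vi, px = _gather_observations(cloud, features)
    for v in np.unique(vi):
        m = vi == v
        cam = poses[v].transform(cloud.points[pi[m]])
        err = np.linalg.norm(intrinsics.project(cam) - px[m], axis=1)
        bad = (err > max_px) | (cam[:, 2] <= 0)
        np.minimum.at(ok, pi[m], ~bad)
    return ok
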