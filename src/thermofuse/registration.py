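"""Cloud-to-mesh registration refinement and landmark displacement error.

The landmark fits (similarity, affine) live in :mod:`thermofuse.transforms`;
this module adds the trimmed iterative-closest-point refinement against the
CT surface and the marker displacement report used to quantify registration
quality (mean / population std / min / max of the per-marker Euclidean
distances).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .transforms import LandmarkSet, umeyama

__all__ = ["RegistrationReport", "MeshProjector", "icp_refine", "displacement_error"]


@dataclass(frozen=True)
class RegistrationReport:
    """Per-marker displacement distances (mm) and their summary statistics."""

    mean: float
    std: float
    min: float
    max: float
    per_marker: dict[str, float]
    transform: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "mean_mm": self.mean,
            "std_mm": self.std,
            "min_mm": self.min,
            "max_mm": self.max,
            "per_marker_mm": self.per_marker,
        }
        if self.transform is not None:
            d["transform"] = np.asarray(self.transform).tolist()
        return d


class MeshProjector:
    """Fast approximate-exact closest-point queries on a triangle mesh.

    Candidate faces come from a KD-tree over face centroids; the exact
    point-triangle distance is then evaluated on the candidates only.
    """

    def __init__(self, mesh: trimesh.Trimesh, k_candidates: int = 8):
        self.mesh = mesh
        self.triangles = mesh.triangles
        self.tree = cKDTree(mesh.triangles_center)
        self.k = min(k_candidates, len(mesh.faces))

    def closest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (closest surface points, distances) for an (N, 3) query."""
        points = np.atleast_2d(points)
        _, cand = self.tree.query(points, k=self.k)
        cand = np.atleast_2d(cand)
        n, k = cand.shape
        tris = self.triangles[cand.ravel()]
        q = np.repeat(points, k, axis=0)
        close = trimesh.triangles.closest_point(tris, q)
        d = np.linalg.norm(close - q, axis=1).reshape(n, k)
        best = d.argmin(axis=1)
        idx = np.arange(n)
        return close.reshape(n, k, 3)[idx, best], d[idx, best]


def icp_refine(
    cloud: np.ndarray,
    target: trimesh.Trimesh,
    init: np.ndarray | None = None,
    max_iter: int = 30,
    tol: float = 1e-4,
    trim_fraction: float = 0.3,
    max_distance_factor: float = 5.0,
    max_points: int = 3000,
    anchors: tuple[np.ndarray, np.ndarray] | None = None,
    anchor_weight: float = 1.0,
    seed: int = 0,
    return_history: bool = False,
):
    """Trimmed point-to-surface ICP refining an initial transform.

    Starting from ``init`` (4x4; identity if omitted, assumed within capture
    range after a landmark fit), each iteration matches every cloud point to
    its closest point on the target surface, discards the worst
    ``trim_fraction`` of correspondences, and solves the rigid update in
    closed form.  A step that would increase the mean trimmed distance is
    rejected and iteration stops, so the recorded distance sequence is
    non-increasing.

    ``anchors`` = (source points, target points) adds known point-to-point
    correspondences (e.g. the registration landmarks) to every update with
    total weight ``anchor_weight`` relative to the surface term — a weighted
    points-and-surfaces registration.  The smooth, nearly left-right
    symmetric bust surface leaves sliding modes that pure surface ICP cannot
    pin down; the anchors remove them.

    Gross outliers beyond ``max_distance_factor`` times the median initial
    distance are excluded once at the start (spurious reconstruction points
    far off the surface would otherwise dominate the trimmed mean).

    Returns the refined 4x4 transform (and the per-iteration mean trimmed
    surface distances when ``return_history``).
    """
    cloud = np.atleast_2d(np.asarray(cloud, float))
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    T = np.eye(4) if init is None else np.asarray(init, float).copy()
    if len(cloud) > max_points:
        rng = np.random.default_rng(seed)
        cloud = cloud[rng.choice(len(cloud), max_points, replace=False)]
    proj = MeshProjector(target)
    moved0 = cloud @ T[:3, :3].T + T[:3, 3]
    _, d0 = proj.closest(moved0)
    med0 = float(np.median(d0))
    gate = d0 <= max(max_distance_factor * med0, 1.0)
    if gate.sum() >= 10:
        cloud = cloud[gate]
    n_keep = max(3, int(np.ceil(len(cloud) * (1.0 - trim_fraction))))
    n_rep = 0
    if anchors is not None:
        a_src = np.atleast_2d(np.asarray(anchors[0], float))
        a_dst = np.atleast_2d(np.asarray(anchors[1], float))
        if a_src.shape != a_dst.shape:
            raise ValueError("anchor source/target shapes differ")
        n_rep = max(1, int(round(anchor_weight * n_keep / len(a_src))))
    history: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        moved = cloud @ T[:3, :3].T + T[:3, 3]
        surf, d = proj.closest(moved)
        keep = np.argsort(d)[:n_keep]
        mean_d = float(d[keep].mean())
        if mean_d > prev:  # reject non-improving step
            T = T_prev
            break
        history.append(mean_d)
        if prev - mean_d < tol and len(history) > 1:
            prev = mean_d
            break
        prev = mean_d
        T_prev = T.copy()
        src_pts, dst_pts = moved[keep], surf[keep]
        if n_rep:
            a_moved = a_src @ T[:3, :3].T + T[:3, 3]
            src_pts = np.vstack([src_pts, np.repeat(a_moved, n_rep, axis=0)])
            dst_pts = np.vstack([dst_pts, np.repeat(a_dst, n_rep, axis=0)])
        R, t, _ = umeyama(src_pts, dst_pts, with_scale=False)
        upd = np.eye(4)
        upd[:3, :3] = R
        upd[:3, 3] = t
        T = upd @ T
    if return_history:
        return T, history
    return T


def displacement_error(a: LandmarkSet, b: LandmarkSet, transform: np.ndarray | None = None) -> RegistrationReport:
    """Per-marker Euclidean displacement between two labeled marker sets.

    Markers are matched by label (an error lists any missing labels); the
    report carries mean, population standard deviation, min and max in mm.
    Symmetric in its arguments and invariant under a common rigid motion.
    """
    try:
        pa = a.aligned_to(b)
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    d = np.linalg.norm(pa - b.points, axis=1)
    return RegistrationReport(
        mean=float(d.mean()),
        std=float(d.std()),  # population (n divisor)
        min=float(d.min()),
        max=float(d.max()),
        per_marker={lb: float(x) for lb, x in zip(b.labels, d)},
        transform=transform,
    )
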