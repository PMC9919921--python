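"""Rigid, similarity and affine 3D transforms and their landmark-based fits.

Two multimodal models — the thermal point cloud from structure-from-motion
and the CT-derived surface — live in different coordinate systems; these are
the maps that bring them together.  The rigid model has exactly six free
parameters (three rotation angles about x, y, z and three translations); the
affine model has the twelve free entries of a 3x4 matrix and additionally
allows scaling and shear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RigidTransform",
    "AffineTransform",
    "LandmarkSet",
    "DegenerateGeometryError",
    "rigid_matrix",
    "affine_apply",
    "fit_similarity",
    "fit_affine",
    "umeyama",
]


class DegenerateGeometryError(ValueError):
    """Raised when a fit's input geometry is rank-deficient."""


@dataclass(frozen=True)
class RigidTransform:
    """Six-parameter rigid motion: rotations alpha, beta, gamma (rad) about
    x, y, z and translation (tx, ty, tz) in mm."""

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0

    N_PARAMS = 6

    def params(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.tx, self.ty, self.tz])

    def matrix(self) -> np.ndarray:
        return rigid_matrix(self)

    def apply(self, points: np.ndarray) -> np.ndarray:
        M = self.matrix()
        return np.atleast_2d(points) @ M[:3, :3].T + M[:3, 3]


def rigid_matrix(t: RigidTransform) -> np.ndarray:
    """Homogeneous 4x4 matrix of the six-parameter rigid model.

    The rotation block is the x-y-z Euler factorization whose (3,1) entry is
    sin(beta); the last column holds the translation and the bottom row is
    (0, 0, 0, 1).
    """
    p = t.params()
    if not np.all(np.isfinite(p)):
        raise ValueError("rigid transform parameters must be finite")
    ca, sa = np.cos(t.alpha), np.sin(t.alpha)
    cb, sb = np.cos(t.beta), np.sin(t.beta)
    cg, sg = np.cos(t.gamma), np.sin(t.gamma)
    M = np.array(
        [
            [cb * cg, ca * sg + sa * sb * cg, sa * sg - ca * sb * cg, t.tx],
            [-cb * sg, ca * cg - sa * sb * sg, sa * cg + ca * sb * sg, t.ty],
            [sb, -sa * cb, ca * cb, t.tz],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return M


@dataclass(frozen=True)
class AffineTransform:
    """Twelve-parameter affine map stored as the free 3x4 block of a 4x4
    homogeneous matrix (bottom row fixed at 0,0,0,1)."""

    M: np.ndarray  # 3x4

    N_PARAMS = 12

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        if M.shape == (4, 4):
            if not np.allclose(M[3], [0, 0, 0, 1]):
                raise ValueError("bottom row must be (0,0,0,1)")
            M = M[:3]
        if M.shape != (3, 4):
            raise ValueError(f"affine matrix must be 3x4, got {M.shape}")
        if abs(np.linalg.det(M[:, :3])) <= 1e-12:
            raise ValueError("linear block is singular")
        object.__setattr__(self, "M", M)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.hstack([np.eye(3), np.zeros((3, 1))]))

    @classmethod
    def from_rigid(cls, t: RigidTransform, scale: float = 1.0) -> "AffineTransform":
        M = rigid_matrix(t)[:3]
        M[:, :3] *= scale
        return cls(M)

    def params(self) -> np.ndarray:
        return self.M.ravel()

    def matrix(self) -> np.ndarray:
        return np.vstack([self.M, [0.0, 0.0, 0.0, 1.0]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        return affine_apply(self, points)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self ∘ other (apply ``other`` first)."""
        return AffineTransform(self.matrix() @ other.matrix())

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix()))


def affine_apply(A: AffineTransform, points: np.ndarray) -> np.ndarray:
    """Apply the homogeneous affine map to an (N, 3) point array."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return pts @ A.M[:, :3].T + A.M[:, 3]


@dataclass(frozen=True)
class LandmarkSet:
    """Labeled 3D marker positions (mm) in one of the two model frames."""

    points: np.ndarray  # (K, 3)
    labels: tuple[str, ...]
    frame: str = "dicom"  # {"sfm", "dicom"}

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[1] != 3:
            raise ValueError("landmark points must be (K, 3)")
        labels = tuple(self.labels)
        if len(labels) != len(pts):
            raise ValueError("labels/points length mismatch")
        if len(set(labels)) != len(labels):
            raise ValueError("landmark labels must be unique")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    def aligned_to(self, other: "LandmarkSet") -> np.ndarray:
        """This set's points reordered to ``other``'s label order."""
        index = {lb: i for i, lb in enumerate(self.labels)}
        missing = [lb for lb in other.labels if lb not in index]
        if missing:
            raise KeyError(f"labels missing from landmark set: {missing}")
        return self.points[[index[lb] for lb in other.labels]]


def _paired_points(src, dst) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(src, LandmarkSet) and isinstance(dst, LandmarkSet):
        return src.aligned_to(dst), dst.points
    return np.atleast_2d(np.asarray(src, float)), np.atleast_2d(np.asarray(dst, float))


def umeyama(src: np.ndarray, dst: np.ndarray, with_scale: bool = True):
    """Closed-form least-squares similarity fit (SVD based).

    Returns (R, t, s) such that ``dst ≈ s * R @ src + t``.
    """
    src = np.atleast_2d(src)
    dst = np.atleast_2d(dst)
    n = len(src)
    if n < 3:
        raise DegenerateGeometryError("need at least 3 correspondences")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    cov = xd.T @ xs / n
    # collinear sources leave the rotation about their axis undetermined
    if np.linalg.matrix_rank(xs, tol=1e-9 * max(1.0, np.abs(xs).max())) < 2:
        raise DegenerateGeometryError("source landmarks are collinear")
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    var_s = (xs**2).sum() / n
    s = float(np.trace(np.diag(D) @ S) / var_s) if with_scale else 1.0
    t = mu_d - s * R @ mu_s
    return R, t, s


def fit_similarity(src, dst) -> tuple[np.ndarray, float]:
    """Least-squares similarity (rotation + translation + isotropic scale)
    mapping ``src`` landmarks onto ``dst``.

    Accepts :class:`LandmarkSet` pairs (matched by label) or plain (N, 3)
    arrays in corresponding order.  Returns (4x4 homogeneous matrix, scale);
    this is what resolves the SfM gauge scale to millimetres.
    """
    s_pts, d_pts = _paired_points(src, dst)
    R, t, s = umeyama(s_pts, d_pts, with_scale=True)
    M = np.eye(4)
    M[:3, :3] = s * R
    M[:3, 3] = t
    return M, s


def fit_affine(src, dst) -> tuple[AffineTransform, float]:
    """Least-squares twelve-parameter affine fit of ``src`` onto ``dst``.

    Needs >= 4 non-coplanar correspondences; returns the transform and the
    RMS residual (mm).
    """
    s_pts, d_pts = _paired_points(src, dst)
    n = len(s_pts)
    if n < 4:
        raise DegenerateGeometryError("need at least 4 correspondences for an affine fit")
    X = np.hstack([s_pts, np.ones((n, 1))])
    scale = max(1.0, float(np.abs(s_pts).max()))
    if np.linalg.matrix_rank(X, tol=1e-9 * scale) < 4:
        raise DegenerateGeometryError(
            "source landmarks are coplanar or collinear: affine parameters are not identifiable"
        )
    M, *_ = np.linalg.lstsq(X, d_pts, rcond=None)
    A = AffineTransform(M.T)
    res = affine_apply(A, s_pts) - d_pts
    rms = float(np.sqrt((res**2).sum(axis=1).mean()))
    return A, rms
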