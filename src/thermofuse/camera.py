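"""Pinhole camera model with Brown–Conrady distortion.

Conventions (package-wide): camera frame has +x right, +y down, +z forward
(optical axis).  A :class:`CameraPose` stores the world→camera map
``x_cam = R @ x_world + t``.  Pixel coordinates are (x=col, y=row) with the
origin at the center of the top-left pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["CameraIntrinsics", "CameraPose", "look_at_pose"]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Focal lengths / principal point (px) and distortion coefficients.

    k1, k2 are radial and p1, p2 tangential terms of the Brown–Conrady model.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    def distort_normalized(self, xn: np.ndarray) -> np.ndarray:
        """Apply distortion to normalized camera coordinates (N, 2)."""
        xn = np.atleast_2d(xn)
        x, y = xn[:, 0], xn[:, 1]
        r2 = x * x + y * y
        radial = 1.0 + self.k1 * r2 + self.k2 * r2 * r2
        xd = x * radial + 2 * self.p1 * x * y + self.p2 * (r2 + 2 * x * x)
        yd = y * radial + self.p1 * (r2 + 2 * y * y) + 2 * self.p2 * x * y
        return np.column_stack([xd, yd])

    def undistort_normalized(self, xd: np.ndarray, iterations: int = 10) -> np.ndarray:
        """Invert the distortion by fixed-point iteration (10 iters suffice
        for the mild distortions of long-wave infrared optics)."""
        xd = np.atleast_2d(xd)
        xn = xd.copy()
        for _ in range(iterations):
            d = self.distort_normalized(xn) - xn
            xn = xd - d
        return xn

    def project(self, points_cam: np.ndarray) -> np.ndarray:
        """Project camera-frame 3D points to (distorted) pixel coordinates."""
        pts = np.atleast_2d(points_cam)
        z = pts[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            xn = pts[:, :2] / z[:, None]
        xd = self.distort_normalized(xn)
        return np.column_stack([self.fx * xd[:, 0] + self.cx, self.fy * xd[:, 1] + self.cy])

    def pixel_to_normalized(self, pix: np.ndarray, undistort: bool = True) -> np.ndarray:
        """Map pixel coordinates to (undistorted) normalized camera coords."""
        pix = np.atleast_2d(pix)
        xd = np.column_stack(
            [(pix[:, 0] - self.cx) / self.fx, (pix[:, 1] - self.cy) / self.fy]
        )
        return self.undistort_normalized(xd) if undistort else xd

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(**{k: float(v) for k, v in d.items()})


class CameraPose:
    """World→camera rigid motion: ``x_cam = R @ x_world + t``."""

    __slots__ = ("R", "t")

    def __init__(self, R: np.ndarray, t: np.ndarray):
        R = np.asarray(R, dtype=float)
        t = np.asarray(t, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("R must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("R is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("det(R) must be +1")
        self.R = R
        self.t = t

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates: C = -R^T t."""
        return -self.R.T @ self.t

    def transform(self, points_world: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points_world) @ self.R.T + self.t

    def compose_after(self, other: "CameraPose") -> "CameraPose":
        """Pose mapping x -> self(other(x))."""
        return CameraPose(self.R @ other.R, self.R @ other.t + self.t)

    def inverse(self) -> "CameraPose":
        return CameraPose(self.R.T, -self.R.T @ self.t)

    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.R
        M[:3, 3] = self.t
        return M

    def __repr__(self) -> str:  # pragma: no cover
        return f"CameraPose(center={np.round(self.center, 3)})"


def look_at_pose(center: np.ndarray, target: np.ndarray, up: np.ndarray) -> CameraPose:
    """Pose of a camera at ``center`` whose optical axis points at ``target``.

    ``up`` is the world direction that should map to the camera's -y axis
    (image up).
    """
    center = np.asarray(center, float)
    fwd = np.asarray(target, float) - center
    fwd = fwd / np.linalg.norm(fwd)
    up = np.asarray(up, float)
    right = np.cross(fwd, up)
    n = np.linalg.norm(right)
    if n < 1e-12:
        raise ValueError("up direction parallel to the viewing direction")
    right /= n
    down = np.cross(fwd, right)
    R = np.vstack([right, down, fwd])  # rows = camera axes in world coords
    t = -R @ center
    return CameraPose(R, t)
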