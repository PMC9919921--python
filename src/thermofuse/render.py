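"""Software z-buffer rasterizer for triangle meshes.

Used in two places: rendering synthetic thermal frames (per-pixel surface
temperature with hidden-surface removal and barycentric interpolation of a
per-vertex field) and building depth buffers for occlusion-aware texture
projection.  Interpolation is perspective-correct (1/z is interpolated
linearly in screen space).
"""

from __future__ import annotations

import numpy as np

from .camera import CameraIntrinsics, CameraPose

__all__ = ["render_mesh", "depth_buffer"]

_NEAR = 1e-6


def _fragments(
    pix: np.ndarray,
    z: np.ndarray,
    values: np.ndarray,
    faces: np.ndarray,
    shape: tuple[int, int],
    max_patch: int = 32,
):
    """Generate candidate fragments (pixel index, depth, value) for a batch
    of front-facing triangles with positive depths."""
    rows, cols = shape
    a, b, c = pix[faces[:, 0]], pix[faces[:, 1]], pix[faces[:, 2]]
    za, zb, zc = z[faces[:, 0]], z[faces[:, 1]], z[faces[:, 2]]
    va, vb, vc = values[faces[:, 0]], values[faces[:, 1]], values[faces[:, 2]]

    lo = np.floor(np.minimum(np.minimum(a, b), c)).astype(int)
    hi = np.ceil(np.maximum(np.maximum(a, b), c)).astype(int)
    lo = np.clip(lo, 0, [cols - 1, rows - 1])
    hi = np.clip(hi, 0, [cols - 1, rows - 1])
    extent = (hi - lo).max(axis=1) + 1
    small = extent <= max_patch
    big_idx = np.nonzero(~small)[0]

    out_pix, out_z, out_v = [], [], []

    def emit(p_idx, depth, val):
        out_pix.append(p_idx)
        out_z.append(depth)
        out_v.append(val)

    # vectorized path for bounded-size patches, chunked to limit memory
    sm = np.nonzero(small)[0]
    patch = int(extent[sm].max()) if len(sm) else 0
    chunk = max(1, 4_000_000 // max(patch * patch, 1))
    offs = np.arange(patch)
    for start in range(0, len(sm), chunk):
        idx = sm[start : start + chunk]
        n = len(idx)
        gx = lo[idx, 0, None, None] + offs[None, None, :]
        gy = lo[idx, 1, None, None] + offs[None, :, None]
        px = np.broadcast_to(gx, (n, patch, patch)).astype(float)
        py = np.broadcast_to(gy, (n, patch, patch)).astype(float)
        ax, ay = a[idx, 0, None, None], a[idx, 1, None, None]
        bx, by = b[idx, 0, None, None], b[idx, 1, None, None]
        cx, cy = c[idx, 0, None, None], c[idx, 1, None, None]
        denom = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
        denom = np.where(np.abs(denom) < 1e-12, np.nan, denom)
        wb = ((px - ax) * (cy - ay) - (py - ay) * (cx - ax)) / denom
        wc = ((bx - ax) * (py - ay) - (by - ay) * (px - ax)) / denom
        wa = 1.0 - wb - wc
        eps = -1e-9
        inside = (wa >= eps) & (wb >= eps) & (wc >= eps)
        inside &= (gx <= hi[idx, 0, None, None]) & (gy <= hi[idx, 1, None, None])
        inside &= (px >= 0) & (px < cols) & (py >= 0) & (py < rows)
        if not inside.any():
            continue
        inv_z = wa / za[idx, None, None] + wb / zb[idx, None, None] + wc / zc[idx, None, None]
        depth = 1.0 / inv_z
        val = depth * (
            wa * va[idx, None, None] / za[idx, None, None]
            + wb * vb[idx, None, None] / zb[idx, None, None]
            + wc * vc[idx, None, None] / zc[idx, None, None]
        )
        sel = inside & np.isfinite(depth) & (depth > _NEAR)
        emit(
            (py[sel].astype(int) * cols + px[sel].astype(int)),
            depth[sel],
            val[sel],
        )

    # fallback loop for large triangles
    for i in big_idx:
        xs = np.arange(lo[i, 0], hi[i, 0] + 1)
        ys = np.arange(lo[i, 1], hi[i, 1] + 1)
        px, py = np.meshgrid(xs.astype(float), ys.astype(float))
        denom = (b[i, 0] - a[i, 0]) * (c[i, 1] - a[i, 1]) - (b[i, 1] - a[i, 1]) * (c[i, 0] - a[i, 0])
        if abs(denom) < 1e-12:
            continue
        wb = ((px - a[i, 0]) * (c[i, 1] - a[i, 1]) - (py - a[i, 1]) * (c[i, 0] - a[i, 0])) / denom
        wc = ((b[i, 0] - a[i, 0]) * (py - a[i, 1]) - (b[i, 1] - a[i, 1]) * (px - a[i, 0])) / denom
        wa = 1.0 - wb - wc
        inside = (wa >= -1e-9) & (wb >= -1e-9) & (wc >= -1e-9)
        if not inside.any():
            continue
        inv_z = wa / za[i] + wb / zb[i] + wc / zc[i]
        depth = 1.0 / inv_z
        val = depth * (wa * va[i] / za[i] + wb * vb[i] / zb[i] + wc * vc[i] / zc[i])
        sel = inside & np.isfinite(depth) & (depth > _NEAR)
        emit((py[sel].astype(int) * cols + px[sel].astype(int)), depth[sel], val[sel])

    if not out_pix:
        return (np.empty(0, dtype=int), np.empty(0), np.empty(0))
    return np.concatenate(out_pix), np.concatenate(out_z), np.concatenate(out_v)


def render_mesh(
    vertices: np.ndarray,
    faces: np.ndarray,
    vertex_values: np.ndarray,
    pose: CameraPose,
    intrinsics: CameraIntrinsics,
    shape: tuple[int, int],
    background: float = np.nan,
    cull_backfaces: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a per-vertex scalar field into an image with hidden-surface
    removal.

    Returns (value image, depth image); background pixels take ``background``
    and depth +inf.  ``shape`` is (rows, cols).
    """
    rows, cols = shape
    cam = pose.transform(vertices)
    z = cam[:, 2]
    pix = intrinsics.project(cam)
    faces = np.asarray(faces, dtype=int)

    ok = (z[faces] > _NEAR).all(axis=1)
    if cull_backfaces:
        # geometric backface test in camera frame (view direction = centroid)
        tri = cam[faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        centroid = tri.mean(axis=1)
        ok &= np.einsum("ij,ij->i", n, centroid) < 0
    faces = faces[ok]
    value_img = np.full(rows * cols, background, dtype=float)
    depth_img = np.full(rows * cols, np.inf)
    if len(faces):
        p_idx, depth, val = _fragments(pix, z, np.asarray(vertex_values, float), faces, shape)
        if len(p_idx):
            np.minimum.at(depth_img, p_idx, depth)
            win = depth <= depth_img[p_idx] * (1 + 1e-12)
            value_img[p_idx[win]] = val[win]
    return value_img.reshape(rows, cols), depth_img.reshape(rows, cols)


def depth_buffer(
    vertices: np.ndarray,
    faces: np.ndarray,
    pose: CameraPose,
    intrinsics: CameraIntrinsics,
    shape: tuple[int, int],
) -> np.ndarray:
    """Depth image (mm along the optical axis) of a mesh; +inf where empty."""
    _, depth = render_mesh(
        vertices, faces, np.zeros(len(vertices)), pose, intrinsics, shape,
        cull_backfaces=True,
    )
    return depth
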