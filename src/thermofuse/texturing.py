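"""Occlusion-aware multi-view thermal texture projection.

After registration, each thermal frame is projected onto the CT surface:
a mesh vertex receives a sample from a view iff it projects inside the
frame, faces the camera, survives a z-buffer occlusion test and is seen
under an acceptable incidence angle.  Samples are blended with cos^n
incidence weights into a per-vertex temperature ("3D thermal shell"),
which can then be colored through a thermal palette.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .camera import CameraIntrinsics, CameraPose
from .ingest import ThermalFrame
from .render import depth_buffer

__all__ = ["TexturedMesh", "VertexSamples", "project_views", "blend_samples", "bake_palette", "IRON_PALETTE"]


@dataclass
class VertexSamples:
    """Per-vertex, per-view temperature samples and incidence cosines.

    ``temps[i, v]`` is NaN where vertex i receives no sample from view v.
    """

    temps: np.ndarray  # (n_vertices, n_views)
    cosines: np.ndarray  # (n_vertices, n_views)
    view_ids: list[int]

    @property
    def support(self) -> np.ndarray:
        return np.isfinite(self.temps).sum(axis=1)


@dataclass
class TexturedMesh:
    """Surface mesh carrying a blended per-vertex temperature texture."""

    mesh: trimesh.Trimesh
    temperature: np.ndarray  # (n_vertices,), NaN where unsupported
    support: np.ndarray  # (n_vertices,) contributing view count
    colors: np.ndarray | None = None  # (n_vertices, 3) uint8

    def __post_init__(self) -> None:
        n = len(self.mesh.vertices)
        if len(self.temperature) != n or len(self.support) != n:
            raise ValueError("attribute length must match vertex count")
        if np.any(np.isfinite(self.temperature) != (self.support >= 1)):
            raise ValueError("temperature must be present exactly where support >= 1")


def _bilinear(grid: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a 2D grid at (x=col, y=row) positions."""
    rows, cols = grid.shape
    x = np.clip(xy[:, 0], 0, cols - 1 - 1e-9)
    y = np.clip(xy[:, 1], 0, rows - 1 - 1e-9)
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    x1 = np.minimum(x0 + 1, cols - 1)
    y1 = np.minimum(y0 + 1, rows - 1)
    fx = x - x0
    fy = y - y0
    return (
        grid[y0, x0] * (1 - fx) * (1 - fy)
        + grid[y0, x1] * fx * (1 - fy)
        + grid[y1, x0] * (1 - fx) * fy
        + grid[y1, x1] * fx * fy
    )


def project_views(
    mesh: trimesh.Trimesh,
    poses: dict[int, CameraPose],
    intrinsics: CameraIntrinsics,
    frames: dict[int, ThermalFrame],
    max_angle_deg: float = 75.0,
    depth_eps_mm: float = 1.0,
    zbuffer_shape: tuple[int, int] | None = None,
) -> VertexSamples:
    """Sample every thermal frame at each visible mesh vertex.

    Mesh and poses must already live in one coordinate frame.  A vertex
    takes a sample from a view iff it (a) projects inside the image, (b) is
    front-facing, (c) passes the z-buffer occlusion test within
    ``depth_eps_mm``, and (d) is seen under incidence <= max_angle_deg.
    Samples are bilinear interpolations of the temperature grid.
    """
    if not frames:
        raise ValueError("no frames to project")
    view_ids = sorted(set(poses) & set(frames))
    if not view_ids:
        raise ValueError("poses and frames share no view ids")
    verts = mesh.vertices
    normals = mesh.vertex_normals
    n = len(verts)
    temps = np.full((n, len(view_ids)), np.nan)
    cosines = np.zeros((n, len(view_ids)))
    cos_max = np.cos(np.radians(max_angle_deg))
    for col, v in enumerate(view_ids):
        pose, frame = poses[v], frames[v]
        rows_px, cols_px = frame.shape
        shape = zbuffer_shape or frame.shape
        zbuf = depth_buffer(verts, mesh.faces, pose, intrinsics, shape)
        cam = pose.transform(verts)
        z = cam[:, 2]
        pix = intrinsics.project(cam)
        inside = (
            (z > 0)
            & (pix[:, 0] >= 0) & (pix[:, 0] <= cols_px - 1)
            & (pix[:, 1] >= 0) & (pix[:, 1] <= rows_px - 1)
        )
        view_dir = verts - pose.center  # world-frame direction camera -> vertex
        vd_norm = np.linalg.norm(view_dir, axis=1)
        cosi = -np.einsum("ij,ij->i", normals, view_dir) / np.maximum(vd_norm, 1e-12)
        facing = cosi > cos_max
        # occlusion: vertex depth against the rasterized depth buffer; use
        # the most permissive of the 4 neighboring depth texels
        cand = inside & facing
        if cand.any():
            sx = (shape[1] - 1) / (cols_px - 1) if zbuffer_shape else 1.0
            sy = (shape[0] - 1) / (rows_px - 1) if zbuffer_shape else 1.0
            px = pix[cand] * [sx, sy]
            x0 = np.clip(np.floor(px[:, 0]).astype(int), 0, shape[1] - 1)
            y0 = np.clip(np.floor(px[:, 1]).astype(int), 0, shape[0] - 1)
            x1 = np.minimum(x0 + 1, shape[1] - 1)
            y1 = np.minimum(y0 + 1, shape[0] - 1)
            neighbors = np.stack([zbuf[y0, x0], zbuf[y0, x1], zbuf[y1, x0], zbuf[y1, x1]])
            finite = np.isfinite(neighbors)
            # at least one neighboring texel must show the surface; depth is
            # compared against the most permissive finite neighbor, and the
            # temperature sample below only uses surface texels
            with np.errstate(invalid="ignore"):
                zref = np.where(finite, neighbors, -np.inf).max(axis=0)
            visible = finite.any(axis=0) & (z[cand] <= zref + depth_eps_mm)
            sel = np.nonzero(cand)[0][visible]
            sel_local = np.nonzero(visible)[0]
        else:
            sel = np.empty(0, dtype=int)
        if len(sel):
            # bilinear interpolation restricted to surface (finite-depth)
            # texels so silhouette samples never blend in the background
            temps[sel, col] = _bilinear_masked(
                frame.temperatures, finite[:, sel_local],
                x0[sel_local], x1[sel_local], y0[sel_local], y1[sel_local],
                px[sel_local],
            )
            cosines[sel, col] = cosi[sel]
    return VertexSamples(temps, cosines, view_ids)


def _bilinear_masked(grid, finite, x0, x1, y0, y1, px):
    """Bilinear interpolation over the subset of the 4 neighboring texels
    that are marked valid; weights renormalized."""
    fx = np.clip(px[:, 0] - x0, 0.0, 1.0)
    fy = np.clip(px[:, 1] - y0, 0.0, 1.0)
    w = np.stack([(1 - fx) * (1 - fy), fx * (1 - fy), (1 - fx) * fy, fx * fy])
    vals = np.stack([grid[y0, x0], grid[y0, x1], grid[y1, x0], grid[y1, x1]])
    w = w * finite
    wsum = w.sum(axis=0)
    # at least the nearest texel is valid, so wsum can only vanish when the
    # valid texels carry zero bilinear weight; fall back to their plain mean
    fallback = wsum <= 1e-12
    out = (w * vals).sum(axis=0) / np.where(fallback, 1.0, wsum)
    if fallback.any():
        cnt = finite.sum(axis=0)
        out = np.where(fallback, (vals * finite).sum(axis=0) / np.maximum(cnt, 1), out)
    return out


def blend_samples(
    mesh: trimesh.Trimesh, samples: VertexSamples, exponent: float = 2.0
) -> TexturedMesh:
    """Blend per-view samples into one temperature per vertex.

    Weighted mean with w = cos^exponent(incidence); vertices without any
    sample are flagged missing (NaN temperature, support 0).  The blended
    value always lies within [min, max] of the vertex's samples.
    """
    w = np.where(np.isfinite(samples.temps), np.maximum(samples.cosines, 0.0) ** exponent, 0.0)
    t = np.where(np.isfinite(samples.temps), samples.temps, 0.0)
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        blended = np.where(wsum > 0, (w * t).sum(axis=1) / wsum, np.nan)
    support = samples.support
    # a sampled vertex with all-zero weights (grazing incidence): plain mean
    degenerate = (support >= 1) & (wsum == 0)
    if degenerate.any():
        blended[degenerate] = np.nanmean(samples.temps[degenerate], axis=1)
    return TexturedMesh(mesh, blended, support)


# a compact iron-style thermal color ramp (cold -> hot)
IRON_PALETTE = np.array(
    [
        [0, 0, 0],
        [32, 0, 100],
        [128, 20, 128],
        [220, 80, 30],
        [255, 160, 0],
        [255, 230, 120],
        [255, 255, 255],
    ],
    dtype=float,
)
MISSING_GRAY = np.array([128, 128, 128], dtype=np.uint8)


def bake_palette(
    textured: TexturedMesh,
    t_range: tuple[float, float],
    palette: np.ndarray = IRON_PALETTE,
) -> TexturedMesh:
    """Map temperatures linearly onto a color ramp.

    ``t_range`` = (t_min, t_max) maps to the first/last palette color;
    values are clamped; vertices without temperature get a sentinel gray.
    """
    t_min, t_max = t_range
    if not t_max > t_min:
        raise ValueError("degenerate temperature range")
    pal = np.asarray(palette, float)
    x = np.clip((textured.temperature - t_min) / (t_max - t_min), 0.0, 1.0)
    pos = x * (len(pal) - 1)
    i0 = np.clip(np.floor(np.nan_to_num(pos)).astype(int), 0, len(pal) - 2)
    f = np.nan_to_num(pos) - i0
    colors = (pal[i0] * (1 - f[:, None]) + pal[i0 + 1] * f[:, None]).round().astype(np.uint8)
    colors[~np.isfinite(textured.temperature)] = MISSING_GRAY
    return TexturedMesh(textured.mesh, textured.temperature, textured.support, colors)
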