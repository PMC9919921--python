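"""Synthetic bust/thyroid scene: the package's self-contained test subject.

Real inputs to the pipeline are (a) an infrared video of a patient's
head/neck/torso swept over ~180°, exported as per-pixel temperature CSVs,
and (b) a contrast CT of the same region.  Neither can ship with the
package, so this module generates a functional stand-in with known ground
truth: a bust-shaped mesh (head width 148 mm and neck width 106 mm by
default, the average adult female dimensions), inner structures (thyroid
lobes + isthmus, trachea, lateral vessels), a rasterized CT-like volume in a
separate "DICOM" frame, a surface temperature field with a thyroid hotspot,
and thermal frames rendered from a horizontal camera arc.

All shapes are signed-distance-field (SDF) primitives: meshes are extracted
with marching cubes and volumes are voxelized exactly from the same SDFs,
so mesh/volume consistency is by construction.  All randomness flows from
``spec.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import trimesh
from skimage import measure

from .camera import CameraIntrinsics, CameraPose, look_at_pose
from .ingest import ThermalFrame, write_thermal_csv
from .render import render_mesh, depth_buffer
from .transforms import LandmarkSet
from .volume import SegmentationMask, VolumeImage, write_dicom_series

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "make_bust",
    "make_inner_structures",
    "rasterize_volume",
    "make_temperature_field",
    "make_landmarks",
    "render_thermal_views",
    "make_fixture",
    "sfm_to_dicom_matrix",
]

AMBIENT_C = 22.0  # background temperature: strong silhouette contrast
HU_LEVELS = {"air": -1000.0, "bust": 40.0, "trachea": -950.0, "thyroid": 150.0, "vessels": 250.0}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of the synthetic acquisition.

    Dimensions in mm, temperatures in °C.  ``noise_sd`` is the thermal
    camera noise (NETD-like, per pixel); ``hu_noise_sd`` the CT noise in HU.
    """

    head_width: float = 148.0
    neck_width: float = 106.0
    torso_width: float = 360.0
    n_views: int = 12
    arc_degrees: float = 180.0
    frame_size: tuple[int, int] = (240, 320)  # (rows, cols)
    focal_px: float = 500.0
    camera_distance: float = 900.0
    skin_baseline: float = 33.0
    hotspot_delta: float = 1.5
    texture_amplitude: float = 0.2
    noise_sd: float = 0.05
    hu_noise_sd: float = 0.0
    voxel_spacing: float = 1.5
    mesh_pitch: float = 3.0
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("head_width", "neck_width", "torso_width", "focal_px",
                     "camera_distance", "voxel_spacing", "mesh_pitch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_views < 2:
            raise ValueError("need at least 2 views")
        if not (0 < self.arc_degrees <= 360):
            raise ValueError("arc_degrees must lie in (0, 360]")


@dataclass
class GroundTruth:
    """Everything the evaluation harness needs: true poses, intrinsics,
    landmarks in both frames, the generating similarity, and the per-vertex
    temperature field."""

    poses: list[CameraPose]
    intrinsics: CameraIntrinsics
    landmarks_sfm: LandmarkSet
    landmarks_dicom: LandmarkSet
    sfm_to_dicom: np.ndarray  # 4x4
    vertex_temperatures: np.ndarray
    landmark_visibility: np.ndarray  # (n_landmarks, n_views) bool


# ---------------------------------------------------------------------------
# signed distance fields (negative inside)


def _sd_superellipsoid(p: np.ndarray, center, semi, power: float) -> np.ndarray:
    q = np.abs((p - np.asarray(center)) / np.asarray(semi))
    r = (q**power).sum(axis=1) ** (1.0 / power)
    return (r - 1.0) * float(min(semi))


def _sd_ellipsoid(p, center, semi):
    return _sd_superellipsoid(p, center, semi, 2.0)


def _sd_elliptic_cylinder(p: np.ndarray, center, semi_xy, half_height: float) -> np.ndarray:
    q = p - np.asarray(center)
    radial = (np.sqrt((q[:, 0] / semi_xy[0]) ** 2 + (q[:, 1] / semi_xy[1]) ** 2) - 1.0) * min(semi_xy)
    axial = np.abs(q[:, 2]) - half_height
    outside = np.sqrt(np.maximum(radial, 0) ** 2 + np.maximum(axial, 0) ** 2)
    inside = np.minimum(np.maximum(radial, axial), 0.0)
    return outside + inside


def _sd_round_box(p: np.ndarray, center, half, radius: float) -> np.ndarray:
    q = np.abs(p - np.asarray(center)) - np.asarray(half)
    outside = np.linalg.norm(np.maximum(q, 0.0), axis=1)
    inside = np.minimum(q.max(axis=1), 0.0)
    return outside + inside - radius


def _smooth_min(a: np.ndarray, b: np.ndarray, k: float) -> np.ndarray:
    h = np.clip(0.5 + 0.5 * (b - a) / k, 0.0, 1.0)
    return b * (1 - h) + a * h - k * h * (1 - h)


def _bust_sdf(spec: SceneSpec):
    """Smooth union of superellipsoid head, elliptic-cylinder neck and
    rounded-box torso.  Scene frame: x right, y anterior (toward the
    cameras), z up; origin at the neck center."""
    head_semi = (spec.head_width / 2.0, 0.60 * spec.head_width, 0.70 * spec.head_width)
    neck_semi = (spec.neck_width / 2.0, 0.85 * spec.neck_width / 2.0)
    torso_half = (spec.torso_width / 2.0 - 25.0, 55.0, 70.0)

    def sdf(p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(p)
        head = _sd_superellipsoid(p, (0.0, 5.0, 140.0), head_semi, 2.5)
        neck = _sd_elliptic_cylinder(p, (0.0, 0.0, 0.0), neck_semi, 60.0)
        torso = _sd_round_box(p, (0.0, -10.0, -130.0), torso_half, 25.0)
        return _smooth_min(_smooth_min(head, neck, 25.0), torso, 30.0)

    return sdf


def _inner_sdfs(spec: SceneSpec) -> dict:
    """Thyroid (two lobes + isthmus anterior to the trachea), tracheal tube
    and two lateral vessels, all strictly inside the neck."""
    def thyroid(p):
        p = np.atleast_2d(p)
        left = _sd_ellipsoid(p, (-14.0, 22.0, -8.0), (7.0, 7.0, 13.0))
        right = _sd_ellipsoid(p, (14.0, 22.0, -8.0), (7.0, 7.0, 13.0))
        isthmus = _sd_ellipsoid(p, (0.0, 24.0, -15.0), (15.0, 4.5, 5.0))
        return _smooth_min(_smooth_min(left, right, 4.0), isthmus, 4.0)

    def trachea(p):
        p = np.atleast_2d(p)
        return _sd_elliptic_cylinder(p, (0.0, 8.0, -10.0), (9.0, 9.0), 48.0)

    def vessels(p):
        p = np.atleast_2d(p)
        lv = _sd_elliptic_cylinder(p, (-30.0, 10.0, -5.0), (4.5, 4.5), 52.0)
        rv = _sd_elliptic_cylinder(p, (30.0, 10.0, -5.0), (4.5, 4.5), 52.0)
        return np.minimum(lv, rv)

    return {"thyroid": thyroid, "trachea": trachea, "vessels": vessels}


def _mesh_from_sdf(sdf, bounds_lo, bounds_hi, pitch: float) -> trimesh.Trimesh:
    lo = np.asarray(bounds_lo, float)
    hi = np.asarray(bounds_hi, float)
    nx, ny, nz = (np.ceil((hi - lo) / pitch).astype(int) + 1)
    x = lo[0] + np.arange(nx) * pitch
    y = lo[1] + np.arange(ny) * pitch
    z = lo[2] + np.arange(nz) * pitch
    # evaluate slice-by-slice to bound memory
    vol = np.empty((nz, ny, nx), dtype=np.float32)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    flat_xy = np.column_stack([xx.ravel(), yy.ravel()])
    for i, zi in enumerate(z):
        pts = np.column_stack([flat_xy, np.full(len(flat_xy), zi)])
        vol[i] = sdf(pts).reshape(ny, nx)
    # force-close the surface at the grid boundary
    for axis in range(3):
        sl = [slice(None)] * 3
        for edge in (0, -1):
            sl[axis] = edge
            vol[tuple(sl)] = np.maximum(vol[tuple(sl)], pitch)
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0, spacing=(pitch, pitch, pitch))
    verts = verts[:, ::-1] + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:  # rebuild with flipped winding (outward normals)
        mesh = trimesh.Trimesh(vertices=verts, faces=faces[:, ::-1], process=False)
    return mesh


_BUST_BOUNDS = lambda spec: (
    np.array([-spec.torso_width / 2.0 - 35.0, -110.0, -245.0]),
    np.array([spec.torso_width / 2.0 + 35.0, 115.0, 260.0]),
)


def make_bust(spec: SceneSpec) -> trimesh.Trimesh:
    """Watertight bust mesh in the scene ("SfM") frame, mm units."""
    lo, hi = _BUST_BOUNDS(spec)
    return _mesh_from_sdf(_bust_sdf(spec), lo, hi, spec.mesh_pitch)


def make_inner_structures(spec: SceneSpec) -> dict[str, trimesh.Trimesh]:
    """Thyroid, trachea and vessel meshes (scene frame)."""
    out = {}
    lo = np.array([-45.0, -15.0, -70.0])
    hi = np.array([45.0, 40.0, 50.0])
    for name, sdf in _inner_sdfs(spec).items():
        out[name] = _mesh_from_sdf(sdf, lo, hi, min(1.5, spec.voxel_spacing))
    return out


def sfm_to_dicom_matrix(spec: SceneSpec) -> np.ndarray:
    """The generating similarity from the scene ("SfM") frame into the DICOM
    frame: a 15° axial rotation plus a translation putting the volume's
    corner at the DICOM origin (scale 1: both frames are metric mm)."""
    ang = np.radians(15.0)
    R = np.array(
        [[np.cos(ang), -np.sin(ang), 0.0], [np.sin(ang), np.cos(ang), 0.0], [0.0, 0.0, 1.0]]
    )
    lo, hi = _BUST_BOUNDS(spec)
    corners = np.array([[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    rot = corners @ R.T
    t = -rot.min(axis=0) + 10.0  # 10 mm margin
    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = t
    return M


def rasterize_volume(spec: SceneSpec) -> tuple[VolumeImage, dict[str, SegmentationMask]]:
    """CT-like voxel volume in the DICOM frame plus exact structure masks.

    Intensities are HU-like levels (air -1000, soft tissue 40, tracheal
    lumen -950, contrast thyroid 150, contrast vessels 250) with optional
    seeded Gaussian noise.
    """
    M = sfm_to_dicom_matrix(spec)
    Rinv = M[:3, :3].T
    t = M[:3, 3]
    lo, hi = _BUST_BOUNDS(spec)
    corners = np.array([[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    dlo = (corners @ M[:3, :3].T + t).min(axis=0) - 10.0
    dhi = (corners @ M[:3, :3].T + t).max(axis=0) + 10.0
    h = spec.voxel_spacing
    nx, ny, nz = (np.ceil((dhi - dlo) / h).astype(int) + 1)
    bust_sdf = _bust_sdf(spec)
    inner = _inner_sdfs(spec)
    vol = np.full((nz, ny, nx), HU_LEVELS["air"], dtype=np.float32)
    masks = {name: np.zeros((nz, ny, nx), dtype=bool) for name in ("bust", *inner)}
    x = dlo[0] + np.arange(nx) * h
    y = dlo[1] + np.arange(ny) * h
    yy, xx = np.meshgrid(y, x, indexing="ij")
    flat_xy = np.column_stack([xx.ravel(), yy.ravel()])
    for i in range(nz):
        w = np.column_stack([flat_xy, np.full(len(flat_xy), dlo[2] + i * h)])
        scene = (w - t) @ Rinv.T
        in_bust = bust_sdf(scene) < 0
        masks["bust"][i] = in_bust.reshape(ny, nx)
        sl = vol[i].ravel()
        sl[in_bust] = HU_LEVELS["bust"]
        for name in ("trachea", "thyroid", "vessels"):
            m = inner[name](scene) < 0
            masks[name][i] = m.reshape(ny, nx)
            sl[m] = HU_LEVELS[name]
        vol[i] = sl.reshape(ny, nx)
    if spec.hu_noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 1)
        vol = vol + rng.normal(0.0, spec.hu_noise_sd, vol.shape).astype(np.float32)
    volume = VolumeImage(vol, (h, h, h), origin=dlo)
    seg = {
        name: SegmentationMask(m, name, (h, h, h), origin=dlo) for name, m in masks.items()
    }
    return volume, seg


# ---------------------------------------------------------------------------
# temperature field and rendering

_HOTSPOT_ANCHOR = np.array([0.0, 40.0, -10.0])  # front of neck over the thyroid


def make_temperature_field(
    bust: trimesh.Trimesh,
    spec: SceneSpec,
    texture: bool = True,
    lowfreq: bool = True,
) -> np.ndarray:
    """Per-vertex skin temperature (°C).

    Baseline + thyroid hotspot (Gaussian falloff, sigma 25 mm, centered on
    the neck surface over the gland) + seeded non-positive low-frequency
    drift + band-limited high-frequency texture (±texture_amplitude) that
    gives the otherwise smooth thermogram enough detail for feature
    detection.
    """
    v = bust.vertices
    field = np.full(len(v), spec.skin_baseline)
    d = np.linalg.norm(v - _HOTSPOT_ANCHOR, axis=1)
    field = field + spec.hotspot_delta * np.exp(-(d**2) / (2 * 25.0**2))
    rng = np.random.default_rng(spec.seed + 2)
    if lowfreq:
        k = rng.normal(size=(3, 3))
        k /= np.linalg.norm(k, axis=1, keepdims=True) * 150.0  # ~150 mm wavelengths
        phase = rng.uniform(0, 2 * np.pi, 3)
        s = np.sin(v @ k.T * 2 * np.pi + phase).sum(axis=1) / 3.0
        field = field - 0.25 * (1.0 + s)  # in [-0.5, 0]: never exceeds the hotspot peak
    if texture and spec.texture_amplitude > 0:
        n_waves = 80
        # wavelengths comfortably above the mesh pitch so the vertex field
        # represents them faithfully from every viewpoint
        wavelengths = rng.uniform(10.0, 30.0, n_waves)  # mm
        dirs = rng.normal(size=(n_waves, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        k = dirs * (2 * np.pi / wavelengths)[:, None]
        phase = rng.uniform(0, 2 * np.pi, n_waves)
        tex = np.cos(v @ k.T + phase) @ rng.uniform(0.5, 1.0, n_waves)
        tex = tex / np.abs(tex).max() * spec.texture_amplitude
        field = field + tex
    return field


_LANDMARK_ANCHORS = {
    "forehead": (0.0, 90.0, 180.0),
    "nose": (0.0, 95.0, 130.0),
    "chin": (0.0, 85.0, 75.0),
    "throat": (0.0, 45.0, 5.0),
    "neck_left": (-52.0, 25.0, 10.0),
    "neck_right": (52.0, 25.0, 10.0),
    "sternum": (0.0, 50.0, -90.0),
}


def make_landmarks(bust: trimesh.Trimesh, spec: SceneSpec) -> LandmarkSet:
    """Seven labeled markers spread over the bust: the nearest mesh vertex
    to each anatomical anchor, hence exactly on the surface."""
    pts = []
    for anchor in _LANDMARK_ANCHORS.values():
        i = int(np.argmin(((bust.vertices - np.asarray(anchor)) ** 2).sum(axis=1)))
        pts.append(bust.vertices[i])
    return LandmarkSet(np.array(pts), tuple(_LANDMARK_ANCHORS), frame="sfm")


def camera_rig(spec: SceneSpec) -> tuple[list[CameraPose], CameraIntrinsics]:
    """n_views cameras on a horizontal arc (left to right across the front),
    all aimed at the neck region."""
    rows, cols = spec.frame_size
    intr = CameraIntrinsics(
        fx=spec.focal_px, fy=spec.focal_px, cx=(cols - 1) / 2.0, cy=(rows - 1) / 2.0
    )
    target = np.array([0.0, 0.0, 20.0])
    half = np.radians(spec.arc_degrees) / 2.0
    angles = np.linspace(-half, half, spec.n_views)
    poses = []
    for a in angles:
        center = target + spec.camera_distance * np.array([np.sin(a), np.cos(a), 0.0])
        poses.append(look_at_pose(center, target, up=np.array([0.0, 0.0, 1.0])))
    return poses, intr


def render_thermal_views(
    bust: trimesh.Trimesh,
    field: np.ndarray,
    spec: SceneSpec,
) -> tuple[list[ThermalFrame], GroundTruth]:
    """Render the per-vertex field into n_views thermal frames with z-buffer
    hidden-surface removal; background pixels are ambient (22 °C).  Also
    assembles the full ground truth (poses, intrinsics, landmarks in both
    frames, the generating similarity)."""
    poses, intr = camera_rig(spec)
    sdf = _bust_sdf(spec)
    for pose in poses:
        if sdf(pose.center[None, :])[0] <= 0:
            raise ValueError("camera center lies inside the bust mesh")
    rng = np.random.default_rng(spec.seed + 3)
    frames = []
    depths = []
    for i, pose in enumerate(poses):
        img, dep = render_mesh(
            bust.vertices, bust.faces, field, pose, intr, spec.frame_size,
            background=AMBIENT_C,
        )
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        frames.append(ThermalFrame(img, frame_index=i))
        depths.append(dep)

    lm_sfm = make_landmarks(bust, spec)
    M = sfm_to_dicom_matrix(spec)
    lm_dicom = LandmarkSet(
        lm_sfm.points @ M[:3, :3].T + M[:3, 3], lm_sfm.labels, frame="dicom"
    )
    rows, cols = spec.frame_size
    vis = np.zeros((len(lm_sfm), len(poses)), dtype=bool)
    for j, pose in enumerate(poses):
        cam = pose.transform(lm_sfm.points)
        pix = intr.project(cam)
        for i, (p, z) in enumerate(zip(pix, cam[:, 2])):
            if z <= 0 or not (0 <= p[0] < cols and 0 <= p[1] < rows):
                continue
            zbuf = depths[j][int(round(p[1])), int(round(p[0]))]
            vis[i, j] = z <= zbuf + 2.0  # mm tolerance at the surface
    gt = GroundTruth(
        poses=poses,
        intrinsics=intr,
        landmarks_sfm=lm_sfm,
        landmarks_dicom=lm_dicom,
        sfm_to_dicom=M,
        vertex_temperatures=np.asarray(field, float),
        landmark_visibility=vis,
    )
    return frames, gt


# ---------------------------------------------------------------------------
# fixture export


def make_fixture(spec: SceneSpec, out_dir: str | Path) -> Path:
    """Write the complete on-disk fixture: thermal CSV frames, a DICOM-like
    CT series, bust/inner meshes, and a ground-truth + manifest JSON."""
    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    bust = make_bust(spec)
    field = make_temperature_field(bust, spec)
    frames, gt = render_thermal_views(bust, field, spec)
    for fr in frames:
        write_thermal_csv(fr, out / "frames" / f"frame_{fr.frame_index:03d}.csv")
    volume, masks = rasterize_volume(spec)
    write_dicom_series(volume, out / "dicom")
    (out / "meshes").mkdir(exist_ok=True)
    bust.export(out / "meshes" / "bust_sfm_frame.ply")
    for name, mesh in make_inner_structures(spec).items():
        mesh.export(out / "meshes" / f"{name}_sfm_frame.stl")
    gt_json = {
        "intrinsics": gt.intrinsics.to_dict(),
        "poses": [
            {"view_id": i, "R": p.R.tolist(), "t": p.t.tolist()} for i, p in enumerate(gt.poses)
        ],
        "landmarks_sfm": {lb: pt.tolist() for lb, pt in zip(gt.landmarks_sfm.labels, gt.landmarks_sfm.points)},
        "landmarks_dicom": {lb: pt.tolist() for lb, pt in zip(gt.landmarks_dicom.labels, gt.landmarks_dicom.points)},
        "sfm_to_dicom": gt.sfm_to_dicom.tolist(),
        "landmark_visibility": gt.landmark_visibility.tolist(),
    }
    (out / "ground_truth.json").write_text(json.dumps(gt_json, indent=1))
    manifest = {"spec": asdict(spec), "n_frames": len(frames)}
    manifest["spec"]["frame_size"] = list(spec.frame_size)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
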