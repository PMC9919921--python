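"""CT-like volume handling: DICOM I/O, threshold segmentation with slice
editing and inter-slice interpolation, surface extraction and smoothing.

Package-wide coordinate convention: a voxel index (slice i, row j, col k)
maps to the world point ``origin + (k*dx, j*dy, i*dz)`` in mm, i.e. world x
runs along columns, y along rows, z along slices.  Meshes extracted here and
the DICOM series share this world frame, so no extra transform is needed at
fusion time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
import trimesh
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy import ndimage
from skimage import measure
from skimage.draw import disk as draw_disk, polygon as draw_polygon

__all__ = [
    "VolumeImage",
    "SegmentationMask",
    "DicomSeriesError",
    "load_dicom_series",
    "write_dicom_series",
    "threshold_mask",
    "edit_mask",
    "interpolate_slices",
    "cleanup_mask",
    "extract_surface",
    "smooth_mesh",
]


class DicomSeriesError(ValueError):
    """Raised for inconsistent or unreadable DICOM series."""


@dataclass
class VolumeImage:
    """Voxel grid with HU-like intensities, axis order (slice, row, col)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]  # (dx, dy, dz) mm along world x, y, z
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxel grid must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive per axis")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def world_grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World x, y, z coordinates of voxel centers (1D per axis)."""
        ns, nr, nc = self.voxels.shape
        dx, dy, dz = self.spacing
        x = self.origin[0] + np.arange(nc) * dx
        y = self.origin[1] + np.arange(nr) * dy
        z = self.origin[2] + np.arange(ns) * dz
        return x, y, z


@dataclass
class SegmentationMask:
    """Binary structure mask sharing its parent volume's geometry."""

    voxels: np.ndarray
    label: str
    spacing: tuple[float, float, float]
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    def count(self) -> int:
        return int(self.voxels.sum())


# ---------------------------------------------------------------------------
# DICOM I/O


def write_dicom_series(volume: VolumeImage, directory: str | Path, series_uid: str | None = None) -> list[Path]:
    """Write a VolumeImage as an uncompressed axial CT DICOM series (one
    int16 slice per file, rescale intercept -1024)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = series_uid or generate_uid()
    study_uid = generate_uid()
    dx, dy, dz = volume.spacing
    intercept, slope = -1024.0, 1.0
    paths = []
    for i, sl in enumerate(volume.voxels):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = i + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            float(volume.origin[0]),
            float(volume.origin[1]),
            float(volume.origin[2] + i * dz),
        ]
        ds.PixelSpacing = [dy, dx]  # row spacing, column spacing
        ds.SliceThickness = dz
        ds.Rows, ds.Columns = sl.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleIntercept = intercept
        ds.RescaleSlope = slope
        raw = np.round((sl - intercept) / slope).astype(np.int16)
        ds.PixelData = raw.tobytes()
        path = directory / f"slice_{i:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def load_dicom_series(directory: str | Path) -> VolumeImage:
    """Load a single-series directory of DICOM slices into a VolumeImage.

    Slices are sorted by position along the slice normal regardless of file
    order; rescale slope/intercept are applied.  Mixed series UIDs or
    missing spacing tags raise :class:`DicomSeriesError`.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in {".dcm", ".ima", ""} and p.is_file())
    if not files:
        raise DicomSeriesError(f"no DICOM files in {directory}")
    slices = []
    uids = set()
    for p in files:
        try:
            ds = pydicom.dcmread(p)
        except Exception as exc:
            raise DicomSeriesError(f"cannot read {p}: {exc}") from exc
        uids.add(getattr(ds, "SeriesInstanceUID", None))
        slices.append(ds)
    if len(uids) != 1:
        raise DicomSeriesError(f"directory mixes {len(uids)} series")
    ds0 = slices[0]
    if not hasattr(ds0, "PixelSpacing") or not hasattr(ds0, "ImagePositionPatient"):
        raise DicomSeriesError("missing PixelSpacing or ImagePositionPatient tags")
    orient = np.array(getattr(ds0, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), float)
    normal = np.cross(orient[:3], orient[3:])
    slices.sort(key=lambda s: float(np.dot(np.array(s.ImagePositionPatient, float), normal)))
    pos = np.array([np.dot(np.array(s.ImagePositionPatient, float), normal) for s in slices])
    if len(slices) > 1:
        steps = np.diff(pos)
        dz = float(steps.mean())
        if dz <= 0 or np.any(np.abs(steps - dz) > 1e-3):
            raise DicomSeriesError("slices are not uniformly spaced")
    else:
        dz = float(getattr(ds0, "SliceThickness", 1.0))
    dy, dx = (float(v) for v in ds0.PixelSpacing)
    vol = []
    for s in slices:
        arr = s.pixel_array.astype(float)
        slope = float(getattr(s, "RescaleSlope", 1.0))
        intercept = float(getattr(s, "RescaleIntercept", 0.0))
        vol.append(arr * slope + intercept)
    origin = np.array(slices[0].ImagePositionPatient, float)
    return VolumeImage(np.stack(vol), (dx, dy, dz), origin)


# ---------------------------------------------------------------------------
# segmentation


def threshold_mask(
    volume: VolumeImage,
    lo: float,
    hi: float,
    label: str = "structure",
    roi: tuple[slice, slice, slice] | None = None,
) -> SegmentationMask:
    """Window threshold: voxel in mask iff lo <= intensity <= hi (and inside
    the optional region-of-interest box, given as index slices)."""
    if lo >= hi:
        raise ValueError(f"need lo < hi, got ({lo}, {hi})")
    m = (volume.voxels >= lo) & (volume.voxels <= hi)
    if roi is not None:
        box = np.zeros_like(m)
        box[roi] = True
        m &= box
    return SegmentationMask(m, label, volume.spacing, volume.origin)


def edit_mask(
    mask: SegmentationMask,
    slice_range: tuple[int, int],
    op: str,
    brush: dict,
) -> SegmentationMask:
    """Add or remove a brush footprint on every slice in [start, stop].

    ``brush`` is either ``{"disk": ((row, col), radius_px)}`` or
    ``{"polygon": [(row, col), ...]}``.  The same edit applied twice is a
    no-op (set union / difference are idempotent).
    """
    start, stop = slice_range
    ns = mask.voxels.shape[0]
    if not (0 <= start <= stop < ns):
        raise IndexError(f"slice range {slice_range} outside [0, {ns - 1}]")
    if op not in {"add", "remove"}:
        raise ValueError("op must be 'add' or 'remove'")
    footprint = np.zeros(mask.voxels.shape[1:], dtype=bool)
    if "disk" in brush:
        center, radius = brush["disk"]
        rr, cc = draw_disk(center, radius, shape=footprint.shape)
    elif "polygon" in brush:
        pts = np.asarray(brush["polygon"], float)
        rr, cc = draw_polygon(pts[:, 0], pts[:, 1], shape=footprint.shape)
    else:
        raise ValueError("brush must specify 'disk' or 'polygon'")
    footprint[rr, cc] = True
    out = mask.voxels.copy()
    for i in range(start, stop + 1):
        if op == "add":
            out[i] |= footprint
        else:
            out[i] &= ~footprint
    return SegmentationMask(out, mask.label, mask.spacing, mask.origin)


def _signed_distance(slice_mask: np.ndarray, spacing_rc: tuple[float, float]) -> np.ndarray:
    """Signed distance (positive inside) of a 2D binary slice."""
    inside = ndimage.distance_transform_edt(slice_mask, sampling=spacing_rc)
    outside = ndimage.distance_transform_edt(~slice_mask, sampling=spacing_rc)
    return inside - outside


def interpolate_slices(mask: SegmentationMask, annotated_slices: list[int]) -> SegmentationMask:
    """Shape-based inter-slice fill between annotated slices.

    Per-slice signed distance transforms are linearly interpolated along the
    slice axis and thresholded at zero, emulating the automatic gap filling
    between hand-annotated CT slices.  Annotated slices are left untouched.
    """
    ann = sorted(set(int(a) for a in annotated_slices))
    ns = mask.voxels.shape[0]
    if len(ann) < 2:
        raise ValueError("need >= 2 annotated slices")
    if ann[0] < 0 or ann[-1] >= ns:
        raise IndexError("annotated slice index out of range")
    for a in ann:
        if not mask.voxels[a].any():
            raise ValueError(f"annotated slice {a} is empty")
    dx, dy, _ = mask.spacing
    out = mask.voxels.copy()
    sdf_cache = {a: _signed_distance(mask.voxels[a], (dy, dx)) for a in ann}
    for a, b in zip(ann[:-1], ann[1:]):
        for i in range(a + 1, b):
            w = (i - a) / (b - a)
            sdf = (1 - w) * sdf_cache[a] + w * sdf_cache[b]
            out[i] = sdf > 0
    return SegmentationMask(out, mask.label, mask.spacing, mask.origin)


def cleanup_mask(mask: SegmentationMask, closing_radius: int = 1) -> SegmentationMask:
    """Keep the largest connected component and morphologically close it
    (the deterministic stand-in for interactive fill/repair tools)."""
    lab, n = ndimage.label(mask.voxels)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = lab == (1 + int(np.argmax(sizes)))
    if closing_radius > 0:
        r = closing_radius
        zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
        ball = zz**2 + yy**2 + xx**2 <= r**2
        keep = ndimage.binary_closing(keep, structure=ball)
    return SegmentationMask(keep, mask.label, mask.spacing, mask.origin)


# ---------------------------------------------------------------------------
# surface extraction and smoothing


def extract_surface(mask: SegmentationMask, presmooth_sigma: float = 0.8) -> trimesh.Trimesh:
    """Marching-cubes isosurface of a binary mask at level 0.5.

    The binary grid is lightly Gaussian-smoothed (``presmooth_sigma`` in
    voxels) before contouring: the raw staircase isosurface overestimates
    area by ~9%, the smoothed one is accurate to ~1-3%.  If smoothing would
    erase the structure entirely (tiny masks), the raw grid is used.
    Vertices are returned in mm world coordinates (voxel index * spacing +
    origin) with outward-oriented faces.
    """
    if not mask.voxels.any():
        raise ValueError("cannot extract a surface from an empty mask")
    dx, dy, dz = mask.spacing
    vol = np.pad(mask.voxels.astype(np.float32), 1)  # close surfaces at the boundary
    if presmooth_sigma > 0:
        smoothed = ndimage.gaussian_filter(vol, presmooth_sigma)
        if smoothed.max() > 0.5:
            vol = smoothed
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.5, spacing=(dz, dy, dx))
    verts = verts[:, ::-1]  # (z, y, x) -> (x, y, z)
    verts = verts - np.array([dx, dy, dz]) + mask.origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:  # rebuild with flipped winding (outward normals)
        mesh = trimesh.Trimesh(vertices=verts, faces=faces[:, ::-1], process=False)
    areas = mesh.area_faces
    if (areas <= 0).any():  # drop exactly-degenerate faces from the grid lattice
        mesh.update_faces(areas > 0)
    return mesh


def smooth_mesh(
    mesh: trimesh.Trimesh,
    iterations: int = 10,
    lambda_pass: float = 0.5,
    mu_pass: float = -0.53,
) -> trimesh.Trimesh:
    """Taubin two-pass Laplacian smoothing (shrink-compensated).

    Connectivity is unchanged; at the defaults the enclosed volume drifts by
    at most a few percent.  ``mu_pass`` must be negative and |mu| > lambda.
    """
    if not np.all(np.isfinite(mesh.vertices)):
        raise ValueError("mesh has non-finite vertices")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    out = mesh.copy()
    if iterations == 0:
        return out
    if mu_pass >= 0:
        raise ValueError("mu_pass must be negative (Taubin inflation pass)")
    trimesh.smoothing.filter_taubin(out, lamb=lambda_pass, nu=-mu_pass, iterations=iterations)
    return out
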