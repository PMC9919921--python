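"""Scene export: textured PLY with a per-vertex temperature property,
inner-structure meshes, the CT series and a JSON manifest tying everything
into the common (DICOM) coordinate system.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh

from .texturing import TexturedMesh, MISSING_GRAY
from .volume import VolumeImage, write_dicom_series

__all__ = ["write_textured_ply", "read_textured_ply", "export_scene"]


def write_textured_ply(textured: TexturedMesh, path: str | Path) -> None:
    """ASCII PLY with x,y,z,nx,ny,nz,red,green,blue and a float
    ``temperature`` vertex property (NaN encoded for missing vertices)."""
    mesh = textured.mesh
    colors = textured.colors
    if colors is None:
        colors = np.tile(MISSING_GRAY, (len(mesh.vertices), 1))
    path = Path(path)
    v = mesh.vertices
    n = mesh.vertex_normals
    t = textured.temperature
    with path.open("w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(v)}\n")
        for prop in ("x", "y", "z", "nx", "ny", "nz"):
            fh.write(f"property float {prop}\n")
        for prop in ("red", "green", "blue"):
            fh.write(f"property uchar {prop}\n")
        fh.write("property float temperature\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for i in range(len(v)):
            fh.write(
                f"{v[i,0]:.6f} {v[i,1]:.6f} {v[i,2]:.6f} "
                f"{n[i,0]:.6f} {n[i,1]:.6f} {n[i,2]:.6f} "
                f"{colors[i,0]} {colors[i,1]} {colors[i,2]} "
                f"{t[i]:.4f}\n"
            )
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_textured_ply(path: str | Path) -> TexturedMesh:
    """Read back a PLY written by :func:`write_textured_ply`."""
    lines = Path(path).read_text().splitlines()
    it = iter(lines)
    n_vert = n_face = 0
    for line in it:
        if line.startswith("element vertex"):
            n_vert = int(line.split()[-1])
        elif line.startswith("element face"):
            n_face = int(line.split()[-1])
        elif line.strip() == "end_header":
            break
    verts = np.empty((n_vert, 3))
    colors = np.empty((n_vert, 3), dtype=np.uint8)
    temps = np.empty(n_vert)
    for i in range(n_vert):
        parts = next(it).split()
        verts[i] = [float(x) for x in parts[0:3]]
        colors[i] = [int(x) for x in parts[6:9]]
        temps[i] = float(parts[9])
    faces = np.empty((n_face, 3), dtype=int)
    for i in range(n_face):
        parts = next(it).split()
        faces[i] = [int(x) for x in parts[1:4]]
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    support = np.isfinite(temps).astype(int)
    return TexturedMesh(mesh, temps, support, colors)


def export_scene(
    thermal_mesh: TexturedMesh,
    inner_meshes: dict[str, trimesh.Trimesh],
    volume: VolumeImage | None,
    out_dir: str | Path,
    frame_tags: dict[str, str] | None = None,
) -> dict:
    """Write the unified scene: textured bust PLY, inner-structure STLs,
    the volume as a DICOM series, and a manifest placing all of them in the
    common DICOM/world frame.

    ``frame_tags`` (name -> frame) are validated: every entry must be
    'dicom'; a mismatch raises ValueError.
    """
    if frame_tags:
        bad = {k: v for k, v in frame_tags.items() if v != "dicom"}
        if bad:
            raise ValueError(f"meshes not in the dicom frame: {bad}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"frame": "dicom", "meshes": []}
    shell_path = out / "thermal_shell.ply"
    write_textured_ply(thermal_mesh, shell_path)
    manifest["meshes"].append(
        {"name": "thermal_shell", "file": shell_path.name, "kind": "textured_surface"}
    )
    for name, mesh in inner_meshes.items():
        p = out / f"{name}.stl"
        mesh.export(p)
        manifest["meshes"].append({"name": name, "file": p.name, "kind": "inner_structure"})
    if volume is not None:
        write_dicom_series(volume, out / "dicom")
        manifest["volume"] = {
            "directory": "dicom",
            "spacing_mm": list(volume.spacing),
            "origin_mm": volume.origin.tolist(),
            "shape": list(volume.shape),
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
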