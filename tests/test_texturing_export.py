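"""Occlusion-aware texture projection, sample blending, palette baking and
scene export."""

import numpy as np
import pytest
import trimesh

from thermofuse.camera import CameraIntrinsics, CameraPose, look_at_pose
from thermofuse.export import export_scene, read_textured_ply, write_textured_ply
from thermofuse.ingest import ThermalFrame
from thermofuse.texturing import (
    IRON_PALETTE,
    MISSING_GRAY,
    TexturedMesh,
    bake_palette,
    blend_samples,
    project_views,
)

INTR = CameraIntrinsics(fx=200.0, fy=200.0, cx=63.5, cy=47.5)
SHAPE = (96, 128)


def plane_mesh(z=100.0, half=120.0, n=11):
    """A subdivided square plane at distance z facing the origin camera."""
    xs = np.linspace(-half, half, n)
    vv, ff = [], []
    for y in xs:
        for x in xs:
            vv.append([x, y, z])
    for j in range(n - 1):
        for i in range(n - 1):
            a = j * n + i
            ff.append([a, a + 1, a + n])
            ff.append([a + 1, a + n + 1, a + n])
    vv = np.array(vv, float)
    ff = np.array(ff)
    # orient faces toward the camera at the origin (true normal -z)
    e1 = vv[ff[0][1]] - vv[ff[0][0]]
    e2 = vv[ff[0][2]] - vv[ff[0][0]]
    if np.cross(e1, e2)[2] > 0:
        ff = ff[:, ::-1]
    return trimesh.Trimesh(vertices=vv, faces=ff, process=False)


def flat_frame(value):
    return ThermalFrame(np.full(SHAPE, float(value)))


class TestProjectViews:
    def test_facing_plane_fully_sampled(self):
        mesh = plane_mesh(half=20.0)  # well inside the frustum
        pose = CameraPose(np.eye(3), np.zeros(3))
        samples = project_views(mesh, {0: pose}, INTR, {0: flat_frame(30.0)})
        assert (samples.support == 1).all()
        np.testing.assert_allclose(samples.temps[:, 0], 30.0)

    def test_back_facing_vertices_unsampled(self):
        mesh = plane_mesh(half=20.0)
        mesh = trimesh.Trimesh(  # reverse winding: normals face away
            np.asarray(mesh.vertices), np.asarray(mesh.faces)[:, ::-1], process=False)
        pose = CameraPose(np.eye(3), np.zeros(3))
        samples = project_views(mesh, {0: pose}, INTR, {0: flat_frame(30.0)})
        assert (samples.support == 0).all()

    def test_occluded_vertices_agree_with_ray_casting_oracle(self):
        """Z-buffer occlusion decisions vs exhaustive ray-triangle
        intersection on a small two-plane scene (~200 vertices)."""
        far = plane_mesh(z=200.0, half=100.0, n=10)  # 100 vertices
        near = plane_mesh(z=100.0, half=25.0, n=10)  # occludes the center
        scene = trimesh.util.concatenate([far, near])
        pose = CameraPose(np.eye(3), np.zeros(3))
        samples = project_views(
            scene, {0: pose}, INTR, {0: flat_frame(31.0)}, depth_eps_mm=1.0
        )
        got_visible = samples.support == 1
        # oracle: cast a ray from the camera to each vertex; visible iff no
        # triangle intersects strictly before the vertex
        tris = scene.triangles
        verts = np.asarray(scene.vertices)
        expected = np.zeros(len(verts), bool)
        for i, v in enumerate(verts):
            ray = v / np.linalg.norm(v)
            t_hit = np.inf
            for tri in tris:
                hit = _ray_triangle(np.zeros(3), ray, tri)
                if hit is not None:
                    t_hit = min(t_hit, hit)
            t_vert = np.linalg.norm(v)
            expected[i] = t_hit >= t_vert - 1e-6
        # compare only on unambiguous vertices (projecting inside the frame,
        # front-facing); silhouette-adjacent vertices are rejected by design
        cam = pose.transform(verts)
        pix = INTR.project(cam)
        inside = (
            (pix[:, 0] > 2) & (pix[:, 0] < SHAPE[1] - 3)
            & (pix[:, 1] > 2) & (pix[:, 1] < SHAPE[0] - 3)
        )
        # exclude vertices within ~2 px of the occluder's silhouette edge
        near_b = near.bounds
        margin = 8.0
        on_edge = np.zeros(len(verts), bool)
        for axis in (0, 1):
            for bound in (near_b[0][axis], near_b[1][axis]):
                # scale occluder edge to the far plane's depth
                proj_edge = bound * 200.0 / 100.0
                on_edge |= np.abs(verts[:, axis] - proj_edge) < margin
        check = inside & ~on_edge
        assert check.sum() >= 60
        np.testing.assert_array_equal(got_visible[check], expected[check])

    def test_no_frames_rejected(self):
        mesh = plane_mesh()
        with pytest.raises(ValueError):
            project_views(mesh, {0: CameraPose(np.eye(3), np.zeros(3))}, INTR, {})


def _ray_triangle(origin, direction, tri):
    """Möller–Trumbore; returns ray parameter t or None."""
    e1 = tri[1] - tri[0]
    e2 = tri[2] - tri[0]
    p = np.cross(direction, e2)
    det = e1 @ p
    if abs(det) < 1e-12:
        return None
    inv = 1.0 / det
    tvec = origin - tri[0]
    u = (tvec @ p) * inv
    if u < -1e-9 or u > 1 + 1e-9:
        return None
    q = np.cross(tvec, e1)
    v = (direction @ q) * inv
    if v < -1e-9 or u + v > 1 + 1e-9:
        return None
    t = (e2 @ q) * inv
    return t if t > 1e-9 else None


class TestBlendSamples:
    def _mesh(self):
        return plane_mesh(half=20.0)

    def test_single_sample_returned_exactly(self):
        mesh = self._mesh()
        pose = CameraPose(np.eye(3), np.zeros(3))
        samples = project_views(mesh, {0: pose}, INTR, {0: flat_frame(33.25)})
        tex = blend_samples(mesh, samples)
        np.testing.assert_allclose(tex.temperature, 33.25)

    def test_equal_samples_blend_to_same_value(self):
        mesh = self._mesh()
        poses = {
            0: look_at_pose([0.0, -20.0, 0.0], [0.0, 0.0, 100.0], [0.0, -1.0, 0.0]),
            1: look_at_pose([0.0, 20.0, 0.0], [0.0, 0.0, 100.0], [0.0, -1.0, 0.0]),
        }
        frames = {0: flat_frame(29.0), 1: flat_frame(29.0)}
        samples = project_views(mesh, poses, INTR, frames)
        tex = blend_samples(mesh, samples)
        have = tex.support > 0
        np.testing.assert_allclose(tex.temperature[have], 29.0)

    def test_blend_bounded_by_sample_range(self, rng):
        mesh = self._mesh()
        poses = {
            0: look_at_pose([0.0, -30.0, 0.0], [0.0, 0.0, 100.0], [0.0, -1.0, 0.0]),
            1: look_at_pose([0.0, 30.0, 0.0], [0.0, 0.0, 100.0], [0.0, -1.0, 0.0]),
        }
        frames = {
            0: ThermalFrame(28 + 4 * rng.random(SHAPE)),
            1: ThermalFrame(28 + 4 * rng.random(SHAPE)),
        }
        samples = project_views(mesh, poses, INTR, frames)
        tex = blend_samples(mesh, samples)
        for i in np.nonzero(tex.support > 0)[0]:
            vals = samples.temps[i][np.isfinite(samples.temps[i])]
            assert vals.min() - 1e-9 <= tex.temperature[i] <= vals.max() + 1e-9

    def test_unsampled_vertices_flagged_missing(self):
        mesh = self._mesh()
        mesh = trimesh.Trimesh(
            np.asarray(mesh.vertices), np.asarray(mesh.faces)[:, ::-1], process=False)
        pose = CameraPose(np.eye(3), np.zeros(3))
        samples = project_views(mesh, {0: pose}, INTR, {0: flat_frame(30.0)})
        tex = blend_samples(mesh, samples)
        assert (tex.support == 0).all()
        assert np.isnan(tex.temperature).all()


class TestBakePalette:
    def _textured(self, temps):
        mesh = plane_mesh(half=20.0, n=int(np.sqrt(len(temps))))
        support = np.isfinite(temps).astype(int)
        return TexturedMesh(mesh, np.asarray(temps, float), support)

    def test_range_endpoints_map_to_palette_ends(self):
        temps = np.full(121, 28.0)
        temps[0] = 38.0
        tex = bake_palette(self._textured(temps), (28.0, 38.0))
        np.testing.assert_array_equal(tex.colors[1], IRON_PALETTE[0].astype(np.uint8))
        np.testing.assert_array_equal(tex.colors[0], IRON_PALETTE[-1].astype(np.uint8))

    def test_missing_vertex_gets_sentinel_gray(self):
        temps = np.full(121, 30.0)
        temps[5] = np.nan
        tex = bake_palette(self._textured(temps), (28.0, 38.0))
        np.testing.assert_array_equal(tex.colors[5], MISSING_GRAY)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            bake_palette(self._textured(np.full(121, 30.0)), (30.0, 30.0))


class TestExport:
    def _textured(self, rng):
        mesh = plane_mesh(half=20.0)
        temps = 28 + 6 * rng.random(len(mesh.vertices))
        temps[3] = np.nan
        support = np.isfinite(temps).astype(int)
        return bake_palette(TexturedMesh(mesh, temps, support), (28.0, 36.0))

    def test_textured_ply_round_trip(self, tmp_path, rng):
        tex = self._textured(rng)
        p = tmp_path / "shell.ply"
        write_textured_ply(tex, p)
        back = read_textured_ply(p)
        np.testing.assert_allclose(np.asarray(back.mesh.vertices), np.asarray(tex.mesh.vertices), atol=1e-5)
        np.testing.assert_array_equal(np.asarray(back.mesh.faces), np.asarray(tex.mesh.faces))
        np.testing.assert_allclose(back.temperature[np.isfinite(tex.temperature)],
                                   tex.temperature[np.isfinite(tex.temperature)], atol=1e-4)
        assert np.isnan(back.temperature[3])
        np.testing.assert_array_equal(back.colors, tex.colors)

    def test_export_scene_manifest_and_containment(self, tmp_path, bust, spec, rng):
        """Exported inner structures stay inside the bust's bounding box."""
        from thermofuse.synthetic import make_inner_structures

        temps = 28 + 6 * rng.random(len(bust.vertices))
        tex = bake_palette(
            TexturedMesh(bust, temps, np.ones(len(bust.vertices), int)), (28.0, 36.0)
        )
        inner = make_inner_structures(spec)
        manifest = export_scene(tex, inner, None, tmp_path / "scene")
        assert len(manifest["meshes"]) == 1 + len(inner)
        assert (tmp_path / "scene" / "thermal_shell.ply").is_file()
        lo, hi = bust.bounds
        for name, mesh in inner.items():
            v = np.asarray(mesh.vertices)
            assert (v >= lo - 1e-6).all() and (v <= hi + 1e-6).all(), name

    def test_frame_tag_mismatch_rejected(self, tmp_path, rng):
        tex = self._textured(rng)
        with pytest.raises(ValueError):
            export_scene(tex, {}, None, tmp_path / "s", frame_tags={"shell": "sfm"})
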