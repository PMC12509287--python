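"""Mesh extraction, refinement, discrete curvature and Willmore energy."""

import numpy as np
import pytest
import trimesh

from sxtmorph import mesh_pipeline as mp
from sxtmorph.phantoms import make_sphere_mask
from sxtmorph.voxel_morphometrics import sphericity


class TestExtractSurface:
    def test_sphere_closed_genus0(self, sphere_mesh_raw):
        mesh = sphere_mesh_raw
        assert mesh.is_watertight
        chi = (len(mesh.vertices) - len(mesh.edges_unique) + len(mesh.faces))
        assert chi == 2

    def test_volume_near_analytic(self, sphere_mesh_raw):
        assert mp.mesh_volume(sphere_mesh_raw) == \
            pytest.approx(4 / 3 * np.pi, rel=0.02)

    def test_bounding_box_matches_mask(self, sphere_mask_005,
                                       sphere_mesh_raw):
        mask, _ = sphere_mask_005
        idx = np.argwhere(mask)
        lo = idx.min(axis=0) * 0.05
        hi = idx.max(axis=0) * 0.05
        assert np.all(np.abs(sphere_mesh_raw.bounds[0] - lo) <= 0.05 + 1e-9)
        assert np.all(np.abs(sphere_mesh_raw.bounds[1] - hi) <= 0.05 + 1e-9)

    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        mesh = mp.extract_surface(mask, 0.1)
        assert mesh.is_watertight
        assert mp.mesh_volume(mesh) > 0

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            mp.extract_surface(np.zeros((4, 4, 4), bool), 0.1)


class TestMeshMeasures:
    def test_icosphere_limits(self):
        ico = trimesh.creation.icosphere(5)
        assert mp.mesh_volume(ico) == pytest.approx(4 * np.pi / 3, rel=5e-3)
        assert mp.mesh_area(ico) == pytest.approx(4 * np.pi, rel=5e-3)

    def test_box_closed_form(self):
        box = trimesh.creation.box(extents=(1, 2, 3))
        assert mp.mesh_volume(box) == pytest.approx(6.0)
        assert mp.mesh_area(box) == pytest.approx(22.0)

    def test_inverted_orientation_absolute(self):
        ico = trimesh.creation.icosphere(3)
        flipped = trimesh.Trimesh(ico.vertices, ico.faces[:, ::-1],
                                  process=False)
        assert mp.mesh_volume(flipped) == pytest.approx(mp.mesh_volume(ico))

    def test_open_mesh_volume_raises(self):
        ico = trimesh.creation.icosphere(2)
        holed = trimesh.Trimesh(ico.vertices, ico.faces[:-1], process=False)
        with pytest.raises(ValueError):
            mp.mesh_volume(holed)


class TestVertexCurvatures:
    @pytest.mark.parametrize("radius", [0.62, 2.0])
    def test_sphere_values(self, radius):
        ico = trimesh.creation.icosphere(4, radius=radius)
        H, K = mp.vertex_curvatures(ico)
        assert H.mean() == pytest.approx(1 / radius, rel=0.03)
        assert K.mean() == pytest.approx(1 / radius ** 2, rel=0.03)

    def test_saddle_negative_gaussian(self):
        # z = x² − y² saddle patch; interior vertices have K < 0
        n = 21
        x, y = np.meshgrid(np.linspace(-1, 1, n), np.linspace(-1, 1, n))
        verts = np.column_stack([x.ravel(), y.ravel(),
                                 (x ** 2 - y ** 2).ravel()])
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces.append([a, a + 1, a + n])
                faces.append([a + 1, a + n + 1, a + n])
        patch = trimesh.Trimesh(verts, np.array(faces), process=False)
        H, K = mp.vertex_curvatures(patch)
        interior = np.isfinite(K)
        assert interior.any()
        assert (K[interior] < 0).mean() > 0.95

    def test_boundary_vertices_flagged(self):
        ico = trimesh.creation.icosphere(2)
        holed = trimesh.Trimesh(ico.vertices, ico.faces[:-1], process=False)
        H, _K = mp.vertex_curvatures(holed)
        assert np.isnan(H).sum() == 3

    def test_concave_sign_convention(self):
        # a sphere with inverted normals is "concave" -> negative H
        ico = trimesh.creation.icosphere(3)
        H, _ = mp.vertex_curvatures(ico)
        assert H.mean() > 0


class TestWillmore:
    # printed per-vacuole mesh statistics: mean H (SD) in µm⁻¹, mean K in
    # µm⁻², surface area in µm², expected WED (µm⁻²) and WE
    TABLE = {
        "A": (1.624, 0.534, 2.657, 4.876, 0.266, None),
        "B": (1.45, 0.79, 2.04, 6.411, 0.687, None),
        "C": (1.637, 1.355, 1.892, 7.664, 2.624, 20.109),
        "E": (0.919, 1.070, 0.893, 8.175, 1.096, None),
        "H": (0.766, 1.015, 0.635, 23.418, 0.982, None),
        "I": (0.825, 1.766, 0.254, 30.858, 3.545, 109.403),
    }

    @pytest.mark.parametrize("key", list(TABLE))
    def test_wed_from_published_stats(self, key):
        mean_h, sd_h, mean_k, area, wed_exp, we_exp = self.TABLE[key]
        wed, we = mp.wed_from_stats(mean_h, sd_h, mean_k, area)
        assert round(wed, 3) == wed_exp
        if we_exp is not None:
            assert round(we, 3) == we_exp

    def test_sphere_wed_zero(self):
        for radius in (0.5, 3.0):
            wed, we = mp.wed_from_stats(1 / radius, 0.0, 1 / radius ** 2,
                                        4 * np.pi * radius ** 2)
            assert wed == pytest.approx(0.0, abs=1e-12)
            assert we == pytest.approx(0.0, abs=1e-12)

    def test_summary_consistent_with_pure_function(self, sphere_mesh_refined):
        summary = mp.curvature_summary(sphere_mesh_refined)
        wed, we = mp.wed_from_stats(summary.mean_H, summary.sd_H,
                                    summary.mean_K, summary.area_um2)
        assert summary.wed == pytest.approx(wed, rel=1e-12)
        assert summary.we == pytest.approx(we, rel=1e-12)

    def test_rigid_motion_invariance(self, sphere_mesh_refined):
        base = mp.curvature_summary(sphere_mesh_refined)
        moved = sphere_mesh_refined.copy()
        transform = trimesh.transformations.rotation_matrix(
            0.7, [1, 2, 3], point=[0.3, -0.2, 0.5])
        moved.apply_transform(transform)
        rotated = mp.curvature_summary(moved)
        assert rotated.wed == pytest.approx(base.wed, rel=1e-6, abs=1e-9)
        assert rotated.we == pytest.approx(base.we, rel=1e-6, abs=1e-8)

    def test_we_scale_invariant(self):
        ico = trimesh.creation.icosphere(3, radius=1.0)
        big = trimesh.creation.icosphere(3, radius=3.0)
        we_small = mp.curvature_summary(ico).we
        we_big = mp.curvature_summary(big).we
        assert we_big == pytest.approx(we_small, abs=1e-6)


class TestGaussBonnet:
    def test_icosphere_machine_precision(self):
        residual, info = mp.gauss_bonnet_residual(trimesh.creation.icosphere(3))
        assert abs(residual) < 1e-9
        assert info["genus"] == 0 and not info["has_holes"]

    def test_torus_genus_one(self):
        torus = trimesh.creation.torus(major_radius=2.0, minor_radius=0.5,
                                       major_sections=48, minor_sections=24)
        residual, info = mp.gauss_bonnet_residual(torus)
        assert info["genus"] == 1
        assert abs(residual) < 1e-9  # total curvature 0 for genus 1

    def test_hole_detected(self):
        ico = trimesh.creation.icosphere(3)
        holed = trimesh.Trimesh(ico.vertices, ico.faces[:-1], process=False)
        residual, info = mp.gauss_bonnet_residual(holed)
        assert info["has_holes"]
        assert abs(residual) > 0.01

    def test_pipeline_meshes_satisfy_identity(self, sphere_mesh_raw,
                                              sphere_mesh_refined):
        for mesh in (sphere_mesh_raw, sphere_mesh_refined):
            summary = mp.curvature_summary(mesh)
            assert summary.gauss_bonnet_total == \
                pytest.approx(4 * np.pi, rel=1e-6)


class TestRefinement:
    def test_volume_preserved_area_reduced(self, sphere_mesh_raw,
                                           sphere_mesh_refined):
        v_pre = mp.mesh_volume(sphere_mesh_raw)
        v_post = mp.mesh_volume(sphere_mesh_refined)
        assert abs(v_post - v_pre) / v_pre < 0.01
        da = (sphere_mesh_raw.area - sphere_mesh_refined.area) \
            / sphere_mesh_raw.area
        assert 0.02 < da < 0.08

    def test_terracing_reduced(self, sphere_mesh_raw, sphere_mesh_refined):
        H_raw, _ = mp.vertex_curvatures(sphere_mesh_raw)
        H_ref, _ = mp.vertex_curvatures(sphere_mesh_refined)
        assert np.nanmax(np.abs(H_ref)) < np.nanmax(np.abs(H_raw))
        assert np.nanstd(H_ref) < np.nanstd(H_raw)

    def test_face_count_reduced(self, sphere_mesh_raw, sphere_mesh_refined):
        assert len(sphere_mesh_refined.faces) < 0.8 * len(
            sphere_mesh_raw.faces)

    def test_smooth_icosphere_near_fixed_point(self):
        ico = trimesh.creation.icosphere(4)
        refined = mp.refine_mesh(ico)
        assert abs(mp.mesh_volume(refined) - mp.mesh_volume(ico)) \
            / mp.mesh_volume(ico) < 1e-3
        assert abs(refined.area - ico.area) / ico.area < 5e-3

    def test_mesh_sphericity_high(self, sphere_mesh_refined):
        s = sphericity(mp.mesh_volume(sphere_mesh_refined),
                       sphere_mesh_refined.area)
        assert s >= 0.99

    def test_open_input_rejected(self):
        ico = trimesh.creation.icosphere(2)
        holed = trimesh.Trimesh(ico.vertices, ico.faces[:-1], process=False)
        with pytest.raises(ValueError):
            mp.refine_mesh(holed)

    def test_taubin_preserves_volume(self, sphere_mesh_raw):
        smoothed = mp.taubin_smooth(sphere_mesh_raw, iterations=15)
        assert abs(smoothed.volume) == \
            pytest.approx(abs(sphere_mesh_raw.volume), rel=1e-9)

    def test_decimation_keeps_curved_regions_denser(self):
        # lobed shape: per-vertex face density after decimation should be
        # higher near the high-curvature neck than on flat-ish lobe tops
        from sxtmorph.phantoms import make_lobed_shape
        mask, _ = make_lobed_shape(2, lobe_radii=(0.5, 0.5),
                                   overlap_frac=0.5, seed=1, voxel_um=0.04)
        mesh = mp.taubin_smooth(mp.extract_surface(mask, 0.04), 10)
        decimated = mp.decimate_quadric(mesh, iterations=10, threshold=1.5)
        assert decimated.is_watertight
        H, K = mp.vertex_curvatures(decimated)
        areas = mp.mixed_vertex_areas(decimated)
        saddle = K < -1.0
        flatish = np.abs(K - np.nanmedian(K)) < 1.0
        if saddle.any() and flatish.any():
            assert areas[saddle].mean() < areas[flatish].mean()
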