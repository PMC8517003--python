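"""Mesh loading, voxelization, material assignment and marker registration."""
import numpy as np
import pytest
import trimesh

from thermopmi import geometry, phantoms
from thermopmi.geometry import (MarkerObservation, MeshError,
                                RegistrationError, TriangleMesh,
                                assign_adipose_shell, assign_substrate,
                                load_surface_mesh, register_marker, save_mesh,
                                validate_scale, voxelize)

from conftest import sphere_mesh

TETRA_PLY = """ply
format ascii 1.0
element vertex 4
property float x
property float y
property float z
element face 4
property list uchar int vertex_indices
end_header
0 0 0
1 0 0
0 1 0
0 0 1
3 0 1 2
3 0 1 3
3 0 2 3
3 1 2 3
"""


class TestLoadSurfaceMesh:
    def test_ascii_ply_tetrahedron_round_trip(self, tmp_path):
        path = tmp_path / "tetra.ply"
        path.write_text(TETRA_PLY)
        mesh = load_surface_mesh(path)
        assert mesh.n_vertices == 4
        assert mesh.n_faces == 4

    def test_obj_cube_reload_preserves_vertex_set(self, tmp_path):
        box = TriangleMesh.from_trimesh(
            trimesh.creation.box(extents=[0.1, 0.1, 0.1]), "cube")
        path = tmp_path / "cube.obj"
        save_mesh(box, path)
        reloaded = load_surface_mesh(path)
        assert reloaded.n_vertices == 8
        assert reloaded.n_faces == 12
        np.testing.assert_allclose(
            np.sort(box.vertices, axis=0), np.sort(reloaded.vertices, axis=0),
            atol=1e-6)

    def test_invalid_face_index_cites_face(self, tmp_path):
        path = tmp_path / "bad.ply"
        path.write_text(TETRA_PLY.replace("3 1 2 3", "3 1 2 9"))
        with pytest.raises(MeshError, match="face .* references vertex 9"):
            load_surface_mesh(path)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(MeshError):
            load_surface_mesh(tmp_path / "nope.ply")


class TestVoxelize:
    def test_axis_aligned_box_has_exact_cube_count(self):
        box = trimesh.creation.box(extents=[0.1, 0.1, 0.1])
        box.apply_translation([0.05, 0.05, 0.05])
        grid = voxelize(TriangleMesh.from_trimesh(box, "box"), dx=0.01)
        assert grid.count("tissue_core") == 1000

    def test_icosphere_count_matches_centre_inclusion_oracle(self,
                                                             sphere_grid):
        # Brute-force oracle: every cube centre tested against the
        # analytic sphere of the same radius.
        idx = np.indices(sphere_grid.dims).reshape(3, -1).T
        centres = sphere_grid.origin + (idx + 0.5) * sphere_grid.dx
        oracle = int((np.linalg.norm(centres, axis=1) < 0.05).sum())
        assert sphere_grid.count("tissue_core") == oracle

    def test_bent_limb_leaves_air_between_tissue_and_substrate(self):
        mesh, _ = phantoms.make_phantom(phantoms.arch_spec())
        grid = voxelize(mesh, dx=0.01)
        grid = assign_substrate(grid, 0.0)
        i = grid.dims[0] // 2
        j = grid.dims[1] // 2
        column = grid.material[i, j, :]
        k_tissue = np.flatnonzero(column == "tissue_core")
        k_substrate = np.flatnonzero(column == "substrate")
        assert k_tissue.size and k_substrate.size
        between = column[k_substrate.max() + 1:k_tissue.min()]
        assert (between == "air").all() and between.size >= 1

    def test_translation_equivariance(self):
        mesh = sphere_mesh(radius=0.03)
        g0 = voxelize(mesh, dx=0.01)
        g1 = voxelize(mesh.translated([0.02, -0.03, 0.01]), dx=0.01)
        assert np.array_equal(g0.material, g1.material)
        np.testing.assert_allclose(g1.origin - g0.origin,
                                   [0.02, -0.03, 0.01], atol=1e-12)

    def test_every_vertex_near_an_occupied_cube(self, sphere_grid):
        mesh = sphere_mesh()
        occ = np.argwhere(sphere_grid.tissue_mask)
        centres = sphere_grid.origin + (occ + 0.5) * sphere_grid.dx
        for v in mesh.vertices[::17]:
            d = np.linalg.norm(centres - v, axis=1).min()
            assert d <= np.sqrt(3) * sphere_grid.dx + 1e-12

    def test_open_mesh_refused_with_repair_hint(self):
        mesh = sphere_mesh()
        open_mesh = TriangleMesh(mesh.vertices, mesh.faces[:-400], "open")
        with pytest.raises(MeshError, match="free-edge"):
            voxelize(open_mesh, dx=0.01)

    def test_dx_larger_than_mesh_extent(self):
        with pytest.raises(MeshError, match="extent"):
            voxelize(sphere_mesh(radius=0.03), dx=0.5)


class TestAssignSubstrate:
    @pytest.fixture()
    def resting_sphere(self):
        m = trimesh.creation.icosphere(subdivisions=3, radius=0.05)
        m.apply_translation([0, 0, 0.05])
        return voxelize(TriangleMesh.from_trimesh(m, "resting"), dx=0.01)

    def test_fills_below_floor_only(self, resting_sphere):
        grid = assign_substrate(resting_sphere, 0.0)
        z = grid.centres_z()
        below = grid.material[:, :, z < 0]
        assert set(np.unique(below)) == {"substrate"}
        assert grid.count("tissue_core") == resting_sphere.count("tissue_core")

    def test_floor_below_grid_is_noop(self, resting_sphere):
        grid = assign_substrate(resting_sphere, -10.0)
        assert np.array_equal(grid.material, resting_sphere.material)

    def test_floor_through_tissue_raises(self, resting_sphere):
        with pytest.raises(ValueError, match="intersects tissue"):
            assign_substrate(resting_sphere, 0.05)


class TestAdiposeShell:
    def test_zero_thickness_gives_no_adipose(self, sphere_grid):
        grid = assign_adipose_shell(sphere_grid, 0.0)
        assert grid.count("tissue_adipose") == 0

    def test_thickness_beyond_radius_makes_all_adipose(self, sphere_grid):
        grid = assign_adipose_shell(sphere_grid, 0.2)
        assert grid.count("tissue_core") == 0
        assert grid.count("tissue_adipose") == sphere_grid.count("tissue_core")

    def test_matches_brute_force_distance_transform(self, sphere_grid):
        thickness = 0.02
        grid = assign_adipose_shell(sphere_grid, thickness)
        tissue = sphere_grid.tissue_mask
        surface = sphere_grid.surface_tissue_mask(facing=("air", "substrate"))
        t_idx = np.argwhere(tissue)
        s_idx = np.argwhere(surface)
        expected = 0
        for cube in t_idx:  # exhaustive pairwise distances
            d = np.sqrt(((s_idx - cube) ** 2).sum(axis=1)).min() * grid.dx
            expected += d < thickness
        assert grid.count("tissue_adipose") == expected

    @pytest.mark.parametrize("t1,t2", [(0.0, 0.01), (0.01, 0.03)])
    def test_monotone_in_thickness(self, sphere_grid, t1, t2):
        a1 = assign_adipose_shell(sphere_grid, t1).material == "tissue_adipose"
        a2 = assign_adipose_shell(sphere_grid, t2).material == "tissue_adipose"
        assert (a2 | ~a1).all()  # a1 subset of a2


class TestRegisterMarker:
    def test_marker_at_surface_cube_centre(self, sphere_grid):
        surf = np.argwhere(sphere_grid.surface_tissue_mask())
        target = tuple(int(v) for v in surf[0])
        centre = sphere_grid.centre(target)
        idx = register_marker(
            sphere_grid, MarkerObservation(1, tuple(centre), "forehead"))
        assert idx == target

    def test_marker_just_outside_snaps_to_same_cube(self, sphere_grid):
        # Topmost surface cube; a marker 1 mm above it snaps back.
        surf = np.argwhere(sphere_grid.surface_tissue_mask())
        top = surf[np.argmax(surf[:, 2])]
        centre = sphere_grid.centre(top)
        on = register_marker(
            sphere_grid, MarkerObservation(1, tuple(centre), "chest"))
        off = register_marker(
            sphere_grid,
            MarkerObservation(2, tuple(centre + [0, 0, 0.001]), "chest"))
        assert on == off

    def test_far_marker_fails(self, sphere_grid):
        with pytest.raises(RegistrationError, match="snap radius"):
            register_marker(
                sphere_grid, MarkerObservation(1, (0.5, 0.5, 0.5), "thigh"),
                snap_radius=0.03)

    def test_non_body_site_rejected(self, sphere_grid):
        with pytest.raises(RegistrationError, match="body site"):
            register_marker(
                sphere_grid, MarkerObservation(1, (0, 0, 0.05), "ambient"))


class TestValidateScale:
    @staticmethod
    def _markers(positions):
        return [MarkerObservation(i + 1, tuple(p), "scale")
                for i, p in enumerate(positions)]

    def test_equal_distances_give_zero_stats(self):
        markers = self._markers([(0, 0, 0), (0.3, 0, 0)])
        out = validate_scale([("1-2", 0.3)], markers)
        assert out.mean_difference_m == 0.0
        assert out.sd_difference_m == 0.0

    def test_hand_arithmetic_difference(self):
        markers = self._markers([(0, 0, 0), (0.3, 0, 0)])
        out = validate_scale([("1-2", 0.29)], markers)
        assert out.table.difference_m.iloc[0] == pytest.approx(-0.01)

    def test_missing_marker_listed(self):
        markers = self._markers([(0, 0, 0), (0.3, 0, 0)])
        with pytest.raises(KeyError, match="3-4"):
            validate_scale([("3-4", 0.1)], markers)

    def test_noisy_manual_measurements_recover_zero_mean(self):
        # 9 pairs with manual values perturbed by N(0, 5 mm): the mean
        # difference lies within 3 standard errors of zero.
        rng = np.random.default_rng(42)
        positions = rng.uniform(0, 1.5, size=(18, 3))
        markers = self._markers(positions)
        manual = []
        for p in range(9):
            a, b = markers[2 * p], markers[2 * p + 1]
            true = np.linalg.norm(a.xyz - b.xyz)
            manual.append((f"{a.marker_id}-{b.marker_id}",
                           true + rng.normal(0, 0.005)))
        out = validate_scale(manual, markers)
        assert abs(out.mean_difference_m) <= 3 * 0.005 / np.sqrt(9)
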