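"""Mesh/landmark/volume I/O, voxelization, surface extraction, distances."""

import numpy as np
import pytest
import trimesh

from boneatlas.errors import GeometryError, MeshIOError
from boneatlas.geometry import (LandmarkSet, ScalarVolume, SurfaceQuery,
                                distance_model, extract_surface, load_nrrd,
                                mesh_volume, read_landmarks, read_stl,
                                save_nrrd, soft_occupancy, voxelize,
                                write_landmarks, write_stl)
from boneatlas.registration import RigidTransform


class TestSTL:
    def test_binary_round_trip(self, tmp_path):
        tet = trimesh.creation.box(extents=(3, 4, 5))
        path = tmp_path / "box.stl"
        write_stl(tet, path)
        back = read_stl(path)
        assert np.allclose(np.sort(back.vertices, axis=0),
                           np.sort(tet.vertices.astype(np.float32), axis=0),
                           atol=1e-6)
        assert abs(back.volume - tet.volume) < 1e-3

    def test_ascii_equals_binary(self, tmp_path):
        mesh = trimesh.creation.icosphere(1, radius=5.0)
        bpath = tmp_path / "b.stl"
        apath = tmp_path / "a.stl"
        write_stl(mesh, bpath)
        apath.write_bytes(trimesh.exchange.stl.export_stl_ascii(mesh).encode())
        mb = read_stl(bpath)
        ma = read_stl(apath)
        assert abs(mb.volume - ma.volume) < 1e-3
        assert len(mb.vertices) == len(ma.vertices)

    def test_truncated_file_rejected(self, tmp_path):
        mesh = trimesh.creation.box()
        path = tmp_path / "t.stl"
        write_stl(mesh, path)
        raw = path.read_bytes()
        path.write_bytes(raw[:len(raw) // 2])
        with pytest.raises(MeshIOError, match="byte"):
            read_stl(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(MeshIOError):
            read_stl(tmp_path / "nope.stl")


class TestLandmarkIO:
    def _eleven(self):
        names = [f"lm_{i}" for i in range(11)]
        pts = np.arange(33, dtype=float).reshape(11, 3) * 0.1
        return LandmarkSet(names, pts)

    def test_round_trip_exact(self, tmp_path):
        lm = self._eleven()
        path = tmp_path / "lm.csv"
        write_landmarks(lm, path)
        back = read_landmarks(path)
        assert back.names == lm.names
        assert np.abs(back.points - lm.points).max() < 1e-12

    def test_duplicate_names_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("name,x,y,z\na,0,0,0\na,1,1,1\n")
        with pytest.raises(MeshIOError, match="duplicate"):
            read_landmarks(path)

    def test_non_numeric_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("name,x,y,z\na,0,zero,0\n")
        with pytest.raises(MeshIOError):
            read_landmarks(path)

    def test_extra_columns_ignored(self, tmp_path, caplog):
        path = tmp_path / "extra.csv"
        path.write_text("name,x,y,z,color\na,1,2,3,red\n")
        lm = read_landmarks(path)
        assert lm.names == ["a"]
        assert np.allclose(lm.points, [[1, 2, 3]])


class TestVoxelize:
    def test_cube_volume(self, unit_cube):
        vol = voxelize(unit_cube, spacing=1.0, padding=2)
        occupied = (vol.values > 0.5).sum() * vol.voxel_volume
        assert abs(occupied - 1000.0) / 1000.0 < 0.05

    def test_sphere_volume(self, icosphere, sphere_volume):
        occupied = (sphere_volume.values > 0.5).sum() * sphere_volume.voxel_volume
        analytic = 4.0 / 3.0 * np.pi * 20.0 ** 3
        # the faceted icosphere itself is ~0.3% under the analytic ball
        assert abs(occupied - analytic) / analytic < 0.02

    def test_open_mesh_rejected(self, unit_cube):
        open_mesh = trimesh.Trimesh(unit_cube.vertices,
                                    unit_cube.faces[:-2], process=False)
        with pytest.raises(GeometryError, match="watertight"):
            voxelize(open_mesh)

    def test_world_convention(self, unit_cube):
        vol = voxelize(unit_cube, spacing=1.0, padding=3)
        # centre voxel of a centred cube must be occupied
        centre_idx = np.round(vol.world_to_index(np.zeros(3))).astype(int)
        assert vol.values[tuple(centre_idx)] == 1.0
        # corner of the padded grid must be empty
        assert vol.values[0, 0, 0] == 0.0

    def test_soft_occupancy_iso_surface_preserved(self, sphere_volume):
        soft = soft_occupancy(sphere_volume, width=4.0)
        assert soft.values.min() >= 0.0 and soft.values.max() <= 1.0
        surf = extract_surface(soft, 0.5)
        r = np.linalg.norm(surf.vertices - surf.vertices.mean(axis=0), axis=1)
        assert abs(r.mean() - 20.0) < 0.6


class TestMeshVolume:
    def test_unit_cube(self):
        cube = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        assert abs(mesh_volume(cube) - 1.0) < 1e-9

    def test_icosphere_close_to_analytic(self):
        m = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
        assert abs(mesh_volume(m) - 4188.79) / 4188.79 < 0.005

    def test_inverted_orientation_fixed(self, caplog):
        cube = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        cube.invert()
        assert abs(mesh_volume(cube) - 1.0) < 1e-9

    def test_rigid_invariance(self, icosphere):
        v0 = mesh_volume(icosphere)
        rng = np.random.default_rng(0)
        q = rng.normal(size=4)
        rot = trimesh.transformations.quaternion_matrix(q / np.linalg.norm(q))
        moved = icosphere.copy()
        moved.apply_transform(rot)
        moved.apply_translation([12.3, -4.5, 6.7])
        assert abs(mesh_volume(moved) - v0) / v0 < 1e-9

    def test_open_mesh_rejected(self, unit_cube):
        broken = trimesh.Trimesh(unit_cube.vertices, unit_cube.faces[:-1],
                                 process=False)
        with pytest.raises(GeometryError):
            mesh_volume(broken)


class TestExtractSurface:
    def test_sphere_radius_recovered(self, sphere_volume):
        surf = extract_surface(sphere_volume, 0.5)
        r = np.linalg.norm(surf.vertices - surf.vertices.mean(axis=0), axis=1)
        assert np.abs(r - 20.0).mean() < 0.6

    def test_iso_outside_range_rejected(self):
        vol = ScalarVolume(np.zeros(3), np.ones(3), np.zeros((5, 5, 5)))
        with pytest.raises(GeometryError):
            extract_surface(vol, 0.5)

    def test_voxelize_extract_round_trip(self, icosphere):
        vol = voxelize(icosphere, spacing=1.0, padding=4)
        surf = extract_surface(vol, 0.5)
        q1 = SurfaceQuery(icosphere)
        q2 = SurfaceQuery(surf)
        _, d12 = q1.closest_point(surf.vertices[::7])
        _, d21 = q2.closest_point(icosphere.vertices[::7])
        assert 0.5 * (d12.mean() + d21.mean()) < 1.0


class TestSurfaceQuery:
    def test_closest_point_matches_brute_force(self, base_mesh):
        from boneatlas.geometry import _closest_point_on_triangles

        q = SurfaceQuery(base_mesh)
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(50, 3)) * 30 + base_mesh.vertices.mean(axis=0)
        _, d = q.closest_point(pts)
        tri = base_mesh.vertices[base_mesh.faces]
        for i in range(len(pts)):
            cp = _closest_point_on_triangles(
                np.repeat(pts[i][None], len(tri), axis=0), tri)
            brute = np.linalg.norm(cp - pts[i], axis=1).min()
            assert abs(d[i] - brute) < 1e-9

    def test_contains_matches_radius_oracle(self, icosphere):
        q = SurfaceQuery(icosphere)
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(200, 3)) * 15
        inside = q.contains(pts)
        r = np.linalg.norm(pts, axis=1)
        clear = np.abs(r - 20.0) > 0.5  # skip the faceting shell
        assert np.array_equal(inside[clear], r[clear] < 20.0)


class TestDistanceModel:
    def test_identical_meshes_zero(self, icosphere):
        dm = distance_model(icosphere, icosphere)
        assert np.abs(dm.signed_distances).max() < 1e-9
        assert dm.hausdorff < 1e-9

    def test_concentric_spheres_signed(self):
        outer = trimesh.creation.icosphere(3, radius=10.0)
        inner = trimesh.creation.icosphere(3, radius=9.0)
        dm = distance_model(outer, inner)  # carrier outside reference
        assert np.all(dm.signed_distances > 0)
        assert abs(dm.signed_distances.mean() - 1.0) < 0.05
        dm2 = distance_model(inner, outer)  # carrier inside reference
        assert np.all(dm2.signed_distances < 0)
        assert abs(dm2.signed_distances.mean() + 1.0) < 0.05

    def test_histogram_counts_conserved(self, base_mesh, icosphere):
        dm = distance_model(base_mesh, icosphere)
        assert dm.counts.sum() == len(base_mesh.vertices)
        assert dm.bin_edges[0] == -np.inf and dm.bin_edges[-1] == np.inf
        inner = dm.bin_edges[1:-1]
        assert inner[0] == -6.0 and inner[-1] == 6.0
        assert np.allclose(np.diff(inner), 0.5)

    def test_sign_convention_against_parity_oracle(self, base_mesh):
        """Negative distance <=> vertex inside the reference mesh."""
        reference = trimesh.creation.icosphere(3, radius=60.0)
        reference.apply_translation(base_mesh.vertices.mean(axis=0))
        dm = distance_model(base_mesh, reference)
        rng = np.random.default_rng(3)
        idx = rng.choice(len(base_mesh.vertices), 100, replace=False)
        centre = reference.vertices.mean(axis=0)
        inside = np.linalg.norm(base_mesh.vertices[idx] - centre, axis=1) < 59.0
        assert np.all(dm.signed_distances[idx][inside] < 0)

    def test_empty_mesh_rejected(self, icosphere):
        empty = trimesh.Trimesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(GeometryError):
            distance_model(empty, icosphere)


class TestNRRD:
    def test_round_trip(self, tmp_path, sphere_volume):
        path = tmp_path / "vol.nrrd"
        save_nrrd(sphere_volume, path)
        back = load_nrrd(path)
        assert np.allclose(back.origin, sphere_volume.origin)
        assert np.allclose(back.spacing, sphere_volume.spacing)
        assert np.allclose(back.values, sphere_volume.values, atol=1e-6)
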