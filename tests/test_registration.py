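"""Registration engines: ICP, affine, demons, inversion, averaging, warps."""

import numpy as np
import pytest
import trimesh

from boneatlas.errors import RegistrationError
from boneatlas.geometry import ScalarVolume
from boneatlas.registration import (AffineTransform, DisplacementField,
                                    RigidTransform, SubjectTransform,
                                    affine_register, average_transforms,
                                    deformable_register, icp_align,
                                    invert_field, invert_subject_transform,
                                    warp_points, warp_volume)

from conftest import blob_volume, textured_blob


def rotation_z(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


class TestICP:
    def test_identity_when_already_aligned(self, base_mesh):
        t, aligned, rms = icp_align(base_mesh, base_mesh, subsample=600, seed=0)
        assert rms < 1e-6
        assert np.abs(t.rotation - np.eye(3)).max() < 1e-6
        assert np.linalg.norm(t.translation) < 1e-5

    def test_recovers_known_rigid_transform(self, base_mesh):
        known = RigidTransform(rotation_z(np.deg2rad(15.0)),
                               np.array([5.0, -3.0, 2.0]))
        moved = base_mesh.copy()
        moved.vertices = known.apply(base_mesh.vertices)
        t, aligned, rms = icp_align(moved, base_mesh, subsample=1200, seed=0,
                                    max_iter=200, tol=1e-9)
        # t should invert the known transform
        comp_r = t.rotation @ known.rotation
        angle = np.arccos(np.clip((np.trace(comp_r) - 1) / 2, -1, 1))
        assert angle < 1e-3
        comp_t = t.rotation @ known.translation + t.translation
        assert np.linalg.norm(comp_t) < 1e-2

    def test_residual_nonincreasing_over_random_poses(self, base_mesh):
        rng = np.random.default_rng(0)
        for _ in range(5):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = rng.uniform(0.02, 0.15)
            k = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
            moved = base_mesh.copy()
            moved.vertices = base_mesh.vertices @ rot.T + rng.normal(size=3)
            _, _, rms = icp_align(moved, base_mesh, subsample=500, seed=1)
            assert rms < 0.5  # converged well below the initial displacement

    def test_equivariance_under_common_rotation(self, base_mesh):
        """Pre-rotating both meshes conjugates the recovered transform."""
        known = RigidTransform(rotation_z(0.2), np.array([2.0, 1.0, -1.0]))
        moved = base_mesh.copy()
        moved.vertices = known.apply(base_mesh.vertices)
        t0, _, _ = icp_align(moved, base_mesh, subsample=800, seed=0)

        r_common = rotation_z(0.5)
        fixed2 = base_mesh.copy()
        fixed2.vertices = base_mesh.vertices @ r_common.T
        moved2 = moved.copy()
        moved2.vertices = moved.vertices @ r_common.T
        t1, _, _ = icp_align(moved2, fixed2, subsample=800, seed=0)
        conjugated = r_common @ t0.rotation @ r_common.T
        assert np.abs(t1.rotation - conjugated).max() < 1e-2

    def test_empty_mesh_rejected(self, base_mesh):
        empty = trimesh.Trimesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(RegistrationError):
            icp_align(empty, base_mesh)


class TestAffine:
    def test_identity_pair(self):
        vol = blob_volume((16, 16, 16), radius=8.0)
        t = affine_register(vol, vol)
        assert np.linalg.norm(t.linear - np.eye(3)) < 1e-2
        assert np.linalg.norm(t.translation) < 0.5

    def test_recovers_known_affine(self):
        """10% anisotropic scale + 10 deg rotation, applied and recovered.

        The fixed image is triaxial and textured so the rotation is
        observable.
        """
        fixed = textured_blob((16, 16, 16), radius=(11.0, 7.0, 5.0))
        known = AffineTransform(rotation_z(np.deg2rad(10.0)) @ np.diag(
            [1.1, 0.95, 1.05]), np.array([1.0, -0.5, 0.8]))
        moving = warp_volume(fixed, known.inverse(), out_grid=fixed)
        rec = affine_register(moving, fixed, linear_bound=0.3,
                              translation_bound=8.0, max_iter=300)
        # the recovered fixed->moving map must match the applied truth:
        # composing it with the truth's inverse is identity over the foreground
        coords = fixed.grid_world_coords().reshape(-1, 3)
        fg = fixed.values.reshape(-1) > 0.05
        comp = known.inverse().apply(rec.apply(coords[fg]))
        disp = np.linalg.norm(comp - coords[fg], axis=1)
        assert disp.mean() < 0.5

    def test_ssd_not_increased(self):
        fixed = blob_volume((16, 16, 16), radius=8.0)
        moving = blob_volume((18, 15, 17), radius=7.0)
        init = AffineTransform.identity()
        t = affine_register(moving, fixed)
        before = np.sum((warp_volume(moving, init, out_grid=fixed).values
                         - fixed.values) ** 2)
        after = np.sum((warp_volume(moving, t, out_grid=fixed).values
                        - fixed.values) ** 2)
        assert after <= before + 1e-9

    def test_all_zero_volume_rejected(self):
        vol = blob_volume((16, 16, 16), radius=8.0)
        zero = vol.like(np.zeros(vol.dims))
        with pytest.raises(RegistrationError):
            affine_register(zero, vol)


def sinusoidal_field(grid: ScalarVolume, amplitude=3.0) -> DisplacementField:
    coords = grid.grid_world_coords()
    ext = np.array(grid.dims) * grid.spacing
    u = np.zeros(grid.dims + (3,))
    u[..., 0] = amplitude * np.sin(2 * np.pi * coords[..., 2] / ext[2])
    u[..., 1] = amplitude * 0.5 * np.sin(2 * np.pi * coords[..., 0] / ext[0])
    return DisplacementField(grid.origin.copy(), grid.spacing.copy(), u)


class TestDemons:
    def test_identity_pair_subvoxel_field(self):
        vol = blob_volume((20, 16, 16), radius=9.0, dims=(40, 32, 32))
        fld = deformable_register(vol, vol, levels=2, iters_per_level=(10, 5))
        assert fld.max_abs < 0.25

    def test_recovers_synthetic_sinusoidal_warp(self):
        fixed = textured_blob((20, 16, 16), radius=12.0, dims=(40, 32, 32))
        known = sinusoidal_field(fixed, amplitude=3.0)
        # moving(x) = fixed sampled through the inverse: moving o phi = fixed
        moving = warp_volume(fixed, known, out_grid=fixed)
        fld = deformable_register(moving, fixed, levels=3,
                                  iters_per_level=(100, 60, 30),
                                  update_sigma=1.5, total_sigma=0.8)
        # recovered map approximates the inverse of the applied warp:
        # composing the two is identity over the foreground
        fg = fixed.values > 0.1
        coords = fixed.grid_world_coords()[fg]
        round_trip = known.apply(fld.apply(coords))
        err = np.linalg.norm(round_trip - coords, axis=-1)
        assert err.mean() < 1.0

    def test_jacobian_positive_on_smooth_problem(self):
        fixed = blob_volume((20, 16, 16), radius=10.0, dims=(40, 32, 32))
        known = sinusoidal_field(fixed, amplitude=2.0)
        moving = warp_volume(fixed, known, out_grid=fixed)
        fld = deformable_register(moving, fixed, levels=2,
                                  iters_per_level=(30, 15))
        assert fld.jacobian_positive_fraction > 0.99

    def test_all_zero_pair_rejected(self):
        grid = ScalarVolume(np.zeros(3), np.ones(3), np.zeros((16, 16, 16)))
        with pytest.raises(RegistrationError):
            deformable_register(grid, grid.like(np.zeros(grid.dims)))

    def test_mismatched_grids_rejected(self):
        a = blob_volume((16, 16, 16))
        b = blob_volume((16, 16, 16), dims=(30, 32, 32))
        with pytest.raises(RegistrationError):
            deformable_register(a, b)


class TestInvertField:
    def grid(self):
        return ScalarVolume(np.zeros(3), np.ones(3), np.zeros((24, 24, 24)))

    def test_zero_field_inverts_to_zero(self):
        fld = DisplacementField.zeros_like(self.grid())
        inv = invert_field(fld, tol=1e-6)
        assert inv.max_abs < 1e-12

    def test_constant_field_inverts_to_negation(self):
        fld = DisplacementField.zeros_like(self.grid())
        fld.u[...] = np.array([1.5, -0.5, 0.25])
        inv = invert_field(fld, tol=1e-4)
        # interior voxels see the exact closed form -c
        assert np.abs(inv.u[8:-8, 8:-8, 8:-8] + fld.u[8:-8, 8:-8, 8:-8]).max() < 1e-3

    def test_smooth_field_round_trip(self):
        grid = self.grid()
        fld = sinusoidal_field(grid, amplitude=1.5)
        inv = invert_field(fld, tol=0.05)
        coords = grid.grid_world_coords().reshape(-1, 3)[::7]
        core = np.all((coords > 4) & (coords < 19), axis=1)
        round_trip = fld.apply(inv.apply(coords[core]))
        err = np.linalg.norm(round_trip - coords[core], axis=1)
        assert err.mean() < 0.1

    def test_nonconvergence_raises(self):
        """A folding field (u_x varying along x, gradient > 1) is not
        invertible; the fixed point must report its residual."""
        grid = self.grid()
        fld = DisplacementField.zeros_like(grid)
        coords = grid.grid_world_coords()
        fld.u[..., 0] = 12.0 * np.sin(2 * np.pi * coords[..., 0] / 24.0)
        with pytest.raises(RegistrationError, match="residual"):
            invert_field(fld, iters=5, tol=1e-4)


class TestWarp:
    def test_identity_transform_noop(self):
        vol = blob_volume((16, 16, 16))
        t = SubjectTransform(AffineTransform.identity(),
                             DisplacementField.zeros_like(vol))
        warped = warp_volume(vol, t, out_grid=vol)
        assert np.abs(warped.values - vol.values).max() < 1e-9
        pts = np.array([[1.0, 2.0, 3.0], [10.0, 5.0, 0.0]])
        assert np.allclose(warp_points(pts, t), pts)

    def test_pure_translation_moves_points(self):
        vol = blob_volume((16, 16, 16))
        t = SubjectTransform(
            AffineTransform(np.eye(3), np.array([2.0, -1.0, 0.5])),
            DisplacementField.zeros_like(vol))
        pts = np.array([[4.0, 4.0, 4.0]])
        assert np.allclose(warp_points(pts, t), pts + [2.0, -1.0, 0.5])

    def test_forward_then_inverse_returns_points(self):
        vol = blob_volume((16, 16, 16), dims=(24, 24, 24))
        fld = sinusoidal_field(vol, amplitude=1.0)
        t = SubjectTransform(
            AffineTransform(np.eye(3) * 1.02, np.array([0.5, 0.0, -0.5])), fld)
        inv = invert_subject_transform(t, tol=0.02)
        pts = np.array([[8.0, 9.0, 10.0], [12.0, 11.0, 9.0], [10.0, 10.0, 12.0]])
        back = inv.apply_points(t.apply_points(pts))
        assert np.linalg.norm(back - pts, axis=1).mean() < 0.1


class TestSerialization:
    def test_transform_round_trip(self, tmp_path):
        vol = blob_volume((16, 16, 16), dims=(20, 20, 20))
        fld = sinusoidal_field(vol, amplitude=1.0)
        t = SubjectTransform(
            AffineTransform(np.eye(3) * 1.05, np.array([1.0, -2.0, 0.5])), fld)
        from boneatlas.registration import load_transform, save_transform

        path = tmp_path / "subject_000.json"
        save_transform(t, path)
        back = load_transform(path)
        assert np.allclose(back.affine.matrix, t.affine.matrix)
        assert back.order == t.order
        assert np.allclose(back.field.u, fld.u, atol=1e-6)
        assert np.allclose(back.field.origin, fld.origin)
        pts = np.array([[5.0, 6.0, 7.0], [10.0, 9.0, 8.0]])
        assert np.allclose(back.apply_points(pts), t.apply_points(pts),
                           atol=1e-5)


class TestAverageTransforms:
    def test_average_of_identical_is_itself(self):
        vol = blob_volume((16, 16, 16))
        fld = sinusoidal_field(vol, amplitude=1.0)
        t = SubjectTransform(AffineTransform(np.eye(3) * 1.1,
                                             np.array([1.0, 0.0, 0.0])), fld)
        avg = average_transforms([t, t, t])
        assert np.allclose(avg.affine.matrix, t.affine.matrix, atol=1e-9)
        assert np.allclose(avg.field.u, fld.u)

    def test_opposite_translations_cancel(self):
        plus = SubjectTransform(
            AffineTransform(np.eye(3), np.array([3.0, 0.0, 0.0])), None)
        minus = SubjectTransform(
            AffineTransform(np.eye(3), np.array([-3.0, 0.0, 0.0])), None)
        avg = average_transforms([plus, minus])
        assert np.linalg.norm(avg.affine.translation) < 1e-9
        assert np.allclose(avg.affine.linear, np.eye(3))

    def test_antisymmetric_fields_cancel(self):
        vol = blob_volume((16, 16, 16))
        fld = sinusoidal_field(vol, amplitude=1.0)
        a = SubjectTransform(AffineTransform.identity(), fld)
        b = SubjectTransform(AffineTransform.identity(), fld.scaled(-1.0))
        avg = average_transforms([a, b])
        assert np.abs(avg.field.u).max() < 1e-12

    def test_empty_list_rejected(self):
        with pytest.raises(RegistrationError):
            average_transforms([])
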