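import numpy as np
import pytest
import trimesh

from meniscus_ssm.mesh_core import TriangleMesh
from meniscus_ssm.registration import (CorrespondedShape, CorrespondenceError,
                                       FFDLattice, RigidTransform,
                                       establish_correspondence, ffd_register,
                                       icp_align, load_lattices, make_lattice,
                                       mean_surface_distance, save_lattices)
from meniscus_ssm.synthetic import (apply_known_deformation,
                                    make_smooth_lattice)

from conftest import random_rotation


def rot_z(deg):
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


class TestRigidTransform:
    def test_rejects_non_orthonormal_rotation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_rejects_reflection(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose_inverse_is_identity(self):
        rng = np.random.default_rng(1)
        tf = RigidTransform(random_rotation(rng, 25), rng.normal(size=3))
        ident = tf.compose(tf.inverse())
        assert ident.rotation_angle_deg() < 1e-10
        np.testing.assert_allclose(ident.translation, 0, atol=1e-12)


class TestICP:
    def test_identity_for_identical_meshes(self, default_mesh):
        res = icp_align(default_mesh, default_mesh)
        assert res.transform.rotation_angle_deg() < 1e-6
        np.testing.assert_allclose(res.transform.translation, 0, atol=1e-6)

    def test_recovers_pure_translation(self, default_mesh):
        moved = default_mesh.transformed(np.eye(3), np.array([5.0, -3.0, 2.0]))
        res = icp_align(moved, default_mesh)
        np.testing.assert_allclose(res.transform.translation,
                                   [-5.0, 3.0, -2.0], atol=1e-3)

    def test_recovers_ten_degree_rotation(self, default_mesh):
        moved = default_mesh.transformed(rot_z(10.0), np.zeros(3))
        res = icp_align(moved, default_mesh)
        assert res.transform.rotation_angle_deg() == pytest.approx(10.0,
                                                                   abs=0.01)

    def test_recovers_random_rigid_motions(self, default_mesh):
        rng = np.random.default_rng(42)
        for _ in range(5):
            r = random_rotation(rng, 30.0)
            t = rng.uniform(-10, 10, 3)
            moved = default_mesh.transformed(r, t)
            res = icp_align(moved, default_mesh)
            err = res.transform.compose(RigidTransform(r, t))
            assert err.rotation_angle_deg() < 0.05
            assert np.linalg.norm(err.translation) < 0.05


class TestFFDLattice:
    def test_zero_lattice_evaluates_to_zero(self, default_mesh):
        lat = make_lattice(default_mesh.vertices.min(axis=0),
                           default_mesh.vertices.max(axis=0), 10.0)
        np.testing.assert_allclose(lat.evaluate(default_mesh.vertices), 0.0)

    def test_json_round_trip(self, tmp_path, default_mesh):
        lat = make_smooth_lattice(default_mesh, spacing=15.0, amplitude=0.4,
                                  seed=3)
        path = tmp_path / "lattices.json"
        save_lattices([lat], path)
        back = load_lattices(path)[0]
        np.testing.assert_allclose(back.displacements, lat.displacements)
        np.testing.assert_allclose(back.origin, lat.origin)
        np.testing.assert_allclose(back.spacing, lat.spacing)

    def test_jacobian_matches_finite_differences(self, default_mesh):
        lat = make_smooth_lattice(default_mesh, spacing=15.0, amplitude=0.5,
                                  seed=4)
        pts = default_mesh.vertices[::200]
        jac = lat.jacobian(pts)
        eps = 1e-5
        for ax in range(3):
            step = np.zeros(3)
            step[ax] = eps
            fd = (lat.evaluate(pts + step) - lat.evaluate(pts - step)) / (2 * eps)
            np.testing.assert_allclose(jac[:, :, ax], fd, atol=1e-6)

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError):
            FFDLattice(np.zeros(3), np.array([1.0, -1.0, 1.0]),
                       np.zeros((4, 4, 4, 3)))


class TestFFDRegistration:
    def test_identical_meshes_give_near_zero_deformation(self, default_mesh):
        res = ffd_register(default_mesh, default_mesh, levels=(20.0, 10.0))
        assert np.abs(res.affine - np.eye(3)).max() < 1e-3
        for lat in res.lattices:
            assert np.abs(lat.displacements).max() < 0.05
        assert res.level_residuals[-1] < 1e-3

    def test_recovers_single_level_known_deformation(self, default_mesh):
        lat = make_smooth_lattice(default_mesh, spacing=10.0, amplitude=0.3,
                                  seed=5)
        deformed = apply_known_deformation(default_mesh, lat)
        res = ffd_register(default_mesh, deformed, levels=(20.0, 10.0, 5.0))
        assert res.level_residuals[-1] < 0.05

    def test_sphere_to_ellipsoid_residuals_non_increasing(self):
        sph = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        sphere = TriangleMesh(np.asarray(sph.vertices), np.asarray(sph.faces),
                              "sphere")
        ellipsoid = TriangleMesh(sphere.vertices * np.array([1.0, 1.0, 1.3]),
                                 sphere.faces.copy(), "ellipsoid")
        res = ffd_register(sphere, ellipsoid, levels=(20.0, 10.0, 5.0))
        r = res.level_residuals
        assert r[0] >= r[1] - 1e-6 and r[1] >= r[2] - 1e-6


class TestCorrespondence:
    def test_shape_vector_layout_is_xs_then_ys_then_zs(self):
        pts = np.arange(12, dtype=float).reshape(4, 3)
        shape = CorrespondedShape.from_points(pts)
        n = shape.n_points
        np.testing.assert_array_equal(shape.coordinates[:n], pts[:, 0])
        np.testing.assert_array_equal(shape.coordinates[n:2 * n], pts[:, 1])
        np.testing.assert_array_equal(shape.coordinates[2 * n:], pts[:, 2])
        np.testing.assert_array_equal(shape.points, pts)
        assert len(shape.coordinates) == 3 * n

    def test_identity_deformation_returns_reference(self, default_mesh):
        ref = CorrespondedShape.from_points(default_mesh.vertices)
        lat = make_lattice(default_mesh.vertices.min(axis=0),
                           default_mesh.vertices.max(axis=0), 20.0)
        out = establish_correspondence(ref, default_mesh, [lat])
        np.testing.assert_allclose(out.points, default_mesh.vertices,
                                   atol=1e-9)

    def test_uniform_scaling_recovered_within_tenth_mm(self, default_mesh):
        c = default_mesh.vertices.mean(axis=0)
        scaled = TriangleMesh(c + 1.1 * (default_mesh.vertices - c),
                              default_mesh.faces.copy(), "scaled")
        ref = CorrespondedShape.from_points(default_mesh.vertices)
        res = ffd_register(default_mesh, scaled)
        out = establish_correspondence(ref, scaled, res)
        err = np.linalg.norm(out.points - scaled.vertices, axis=1)
        assert err.max() < 0.1

    def test_gate_raises_with_offending_indices(self, default_mesh):
        far = TriangleMesh(default_mesh.vertices + 30.0,
                           default_mesh.faces.copy(), "far")
        ref = CorrespondedShape.from_points(default_mesh.vertices)
        lat = make_lattice(default_mesh.vertices.min(axis=0) - 1,
                           default_mesh.vertices.max(axis=0) + 31, 20.0)
        with pytest.raises(CorrespondenceError) as exc:
            establish_correspondence(ref, far, [lat], gate=5.0)
        assert len(exc.value.indices) == len(default_mesh.vertices)


def test_mean_surface_distance_zero_on_self(default_mesh):
    assert mean_surface_distance(default_mesh, default_mesh) < 1e-12
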