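import numpy as np
import pytest
import trimesh

from meniscus_ssm.mesh_core import TriangleMesh
from meniscus_ssm.morphometry import (PoseError, change_rate, coverage_areas,
                                      coverage_percentage, find_landmarks,
                                      measure_record,
                                      mode_change_table, rdl,
                                      standardize_pose, total_contact_area)
from meniscus_ssm.registration import CorrespondedShape
from meniscus_ssm.shape_model import build_ssm
from meniscus_ssm.synthetic import annulus_slab, generate_meniscus, MeniscusParams

from conftest import random_rotation


class TestDerivedIndices:
    def test_coverage_percentage_examples(self):
        assert coverage_percentage(3.0, 1.0) == pytest.approx(0.75)
        assert coverage_percentage(5.0, 0.0) == 1.0
        with pytest.raises(ValueError):
            coverage_percentage(0.0, 1.0)

    def test_total_contact_area(self):
        assert total_contact_area(157.08, 196.35) == pytest.approx(353.43)
        assert total_contact_area(0.0, 7.0) == 7.0
        with pytest.raises(ValueError):
            total_contact_area(-1.0, 1.0)

    @pytest.mark.parametrize("args,expected", [((30, 30, 30), 1.0),
                                               ((15.5, 20, 11), 1.0)])
    def test_rdl_examples(self, args, expected):
        assert rdl(*args) == pytest.approx(expected)

    def test_rdl_scale_invariant(self):
        assert rdl(12.0, 18.0, 14.0) == pytest.approx(rdl(24.0, 36.0, 28.0))
        with pytest.raises(ValueError):
            rdl(1.0, 0.0, 0.0)

    def test_change_rate_examples(self):
        assert change_rate(10.0, 12.0, 8.0) == pytest.approx(0.4)
        assert change_rate(5.0, 3.0, 3.0) == 0.0
        assert change_rate(10.0, 8.0, 12.0) == pytest.approx(-0.4)
        with pytest.raises(ValueError):
            change_rate(0.0, 1.0, -1.0)


class TestStandardizePose:
    def test_canonical_mesh_recovers_identity_frame(self, default_mesh):
        _, frame = standardize_pose(default_mesh)
        angle = np.degrees(np.arccos(np.clip(
            (np.trace(frame.axes) - 1) / 2, -1, 1)))
        assert angle < 1.0

    def test_invariant_to_rigid_motion(self, default_mesh):
        rng = np.random.default_rng(3)
        moved = default_mesh.transformed(random_rotation(rng, 170.0),
                                         np.array([12.0, -4.0, 9.0]))
        std_a, _ = standardize_pose(default_mesh)
        std_b, _ = standardize_pose(moved)
        np.testing.assert_allclose(std_b.vertices, std_a.vertices, atol=0.1)

    def test_left_knee_mirrored_measurements_match_right(self, default_mesh):
        mirrored = TriangleMesh(
            default_mesh.vertices * np.array([-1.0, 1.0, 1.0]),
            default_mesh.faces[:, ::-1].copy(), "left")
        rec_r = measure_record(default_mesh, side="right")
        rec_l = measure_record(mirrored, side="left")
        for name in rec_r.PARAMETERS:
            assert getattr(rec_l, name) == pytest.approx(
                getattr(rec_r, name), rel=1e-6)

    def test_sphere_has_no_crescent_frame(self):
        sph = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        mesh = TriangleMesh(np.asarray(sph.vertices), np.asarray(sph.faces))
        with pytest.raises(PoseError):
            standardize_pose(mesh)


class TestLandmarksAndDistances:
    def test_landmarks_match_analytic_ground_truth(self, default_mesh_truth):
        mesh, truth = default_mesh_truth
        std, frame = standardize_pose(mesh)
        landmarks = find_landmarks(std)
        for name, expected in truth.landmarks.items():
            world = frame.to_world(landmarks[name])
            assert np.linalg.norm(world - expected) < 0.5, name

    def test_distances_match_analytic_sweep_geometry(self, default_mesh_truth):
        mesh, truth = default_mesh_truth
        record = measure_record(mesh)
        for name, expected in truth.distances.items():
            assert getattr(record, name) == pytest.approx(expected, rel=0.02)

    def test_landmarks_scale_linearly(self, default_mesh):
        std, _ = standardize_pose(default_mesh)
        doubled = TriangleMesh(std.vertices * 2.0, std.faces.copy())
        lm1 = find_landmarks(std)
        lm2 = find_landmarks(doubled)
        for name in lm1:
            np.testing.assert_allclose(lm2[name], 2.0 * lm1[name], atol=1e-9)

    def test_symmetric_horns_give_equal_widths_and_lengths(self, default_mesh):
        record = measure_record(default_mesh)
        assert record.PH_Wid == pytest.approx(record.AH_Wid, rel=1e-6)
        assert record.PH_Len == pytest.approx(record.AH_Len, rel=1e-6)


class TestCoverageAreas:
    def test_half_annulus_analytic_areas(self):
        mesh = annulus_slab(r_inner=10.0, r_outer=15.0, angle_deg=180.0)
        cov, gap, con = coverage_areas(mesh)
        assert cov == pytest.approx(0.5 * np.pi * (15 ** 2 - 10 ** 2),
                                    rel=0.01)
        assert con == pytest.approx(cov, rel=0.01)
        assert gap == pytest.approx(0.5 * np.pi * 10 ** 2, rel=0.01)

    def test_full_annulus_gap_is_inner_disc(self):
        mesh = annulus_slab(r_inner=10.0, r_outer=15.0, angle_deg=360.0)
        _, gap, _ = coverage_areas(mesh)
        assert gap == pytest.approx(np.pi * 10 ** 2, rel=0.01)

    @pytest.mark.parametrize("s", [0.5, 2.0])
    def test_areas_scale_quadratically(self, default_mesh, s):
        std, _ = standardize_pose(default_mesh)
        scaled = TriangleMesh(std.vertices * s, std.faces.copy())
        base = coverage_areas(std)
        out = coverage_areas(scaled)
        for a, b in zip(out, base):
            assert a == pytest.approx(s ** 2 * b, rel=0.005)


class TestRecords:
    def test_record_identities_hold_exactly(self, default_mesh):
        rec = measure_record(default_mesh)
        assert rec.Cov_Pct == pytest.approx(
            rec.Cov_Area / (rec.Gap_Area + rec.Cov_Area), abs=1e-12)
        assert rec.Tcon_Area == pytest.approx(rec.Gap_Area + rec.Con_Area,
                                              abs=1e-12)
        assert rec.RDL == pytest.approx(
            rec.PA_Dis / (0.5 * (rec.PH_Len + rec.AH_Len)), abs=1e-12)

    def test_rigid_motion_invariance_of_all_measurements(self, default_mesh):
        rng = np.random.default_rng(8)
        moved = default_mesh.transformed(random_rotation(rng, 120.0),
                                         np.array([-20.0, 6.0, 40.0]))
        rec_a = measure_record(default_mesh)
        rec_b = measure_record(moved)
        for name in rec_a.PARAMETERS:
            assert getattr(rec_b, name) == pytest.approx(
                getattr(rec_a, name), rel=0.005), name


class TestModeChangeTable:
    def test_pure_size_mode_matches_scaling_calculus(self, default_mesh):
        base = CorrespondedShape.from_points(default_mesh.vertices)
        shapes = [CorrespondedShape(base.coordinates * (1 + b), f"s{i}")
                  for i, b in enumerate([-0.03, -0.01, 0.01, 0.03])]
        model = build_ssm(shapes)
        table = mode_change_table(model, default_mesh.faces, k_modes=2)
        dist_cols = ["dPH_Wid", "dAH_Wid", "dPA_Dis", "dPH_Len", "dAH_Len",
                     "dLPH_Thic", "dLPH_Wid"]
        area_cols = ["dCov_Area", "dCon_Area", "dTcon_Area"]
        d_ref = table.loc[1, "dPA_Dis"]
        assert d_ref > 0
        for col in dist_cols:
            assert table.loc[1, col] == pytest.approx(d_ref, rel=0.05), col
        for col in area_cols:
            assert table.loc[1, col] == pytest.approx(2 * d_ref, rel=0.05), col
        assert abs(table.loc[1, "dCov_Pct"]) < 0.05 * d_ref
        assert abs(table.loc[1, "dRDL"]) < 0.05 * d_ref
        # beyond the model's single mode the rows are identically zero
        assert (table.loc[2] == 0).all()

    def test_openness_mode_raises_rdl(self):
        shapes = []
        for i, da in enumerate([-4.0, -1.5, 1.5, 4.0]):
            mesh, _ = generate_meniscus(
                MeniscusParams(opening_half_angle=60.0 + da))
            shapes.append(
                CorrespondedShape.from_points(mesh.vertices, f"s{i}"))
        model = build_ssm(shapes)
        faces = generate_meniscus(MeniscusParams())[0].faces
        table = mode_change_table(model, faces, k_modes=1)
        score_sign = np.corrcoef(model.scores[:, 0],
                                 [-4.0, -1.5, 1.5, 4.0])[0, 1]
        # wider opening angle means a larger inter-horn distance relative to
        # horn length: dRDL carries the sign of the opening direction
        assert np.sign(table.loc[1, "dRDL"]) == np.sign(score_sign)
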