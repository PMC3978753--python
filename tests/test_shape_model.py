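import numpy as np
import pytest
from scipy.linalg import subspace_angles

from meniscus_ssm.registration import CorrespondedShape
from meniscus_ssm.shape_model import (ShapeModel, build_ssm, procrustes_align,
                                      project, reconstruction_residual,
                                      sample_mode, variance_explained)

from conftest import random_rotation


def linear_cohort(n_subjects=50, n_points=120, noise=0.01, seed=2):
    """Shapes from a known 3-mode linear model: mean + sum z_k s_k u_k."""
    rng = np.random.default_rng(seed)
    dim = 3 * n_points
    mean = rng.uniform(-20, 20, dim)
    basis = np.linalg.qr(rng.normal(size=(dim, 3)))[0].T       # (3, dim)
    sds = np.array([3.0, 2.0, 1.0])
    z = rng.normal(size=(n_subjects, 3))
    data = mean + (z * sds) @ basis + rng.normal(0, noise, (n_subjects, dim))
    shapes = [CorrespondedShape(row, f"s{i}") for i, row in enumerate(data)]
    return shapes, mean, basis, sds, z


class TestBuildSSM:
    def test_identical_shapes_have_zero_modes(self):
        shape = CorrespondedShape(np.arange(30, dtype=float))
        model = build_ssm([shape] * 5)
        assert model.n_modes == 0
        np.testing.assert_allclose(model.mean_shape, shape.coordinates)

    def test_two_shapes_one_mode_mean_is_midpoint(self):
        a = CorrespondedShape(np.zeros(30), "a")
        b = CorrespondedShape(np.arange(30, dtype=float), "b")
        model = build_ssm([a, b])
        assert model.n_modes == 1
        np.testing.assert_allclose(model.mean_shape,
                                   (a.coordinates + b.coordinates) / 2)

    def test_three_mode_cohort_recovers_generative_subspace(self):
        shapes, _, basis, sds, _ = linear_cohort()
        model = build_ssm(shapes)
        assert variance_explained(model, 3) >= 0.99
        angle = subspace_angles(model.modes[:3].T, basis.T).max()
        assert np.degrees(angle) < 2.0
        np.testing.assert_allclose(model.mode_stddevs[:3], sds, rtol=0.15)

    def test_exact_reconstruction_of_training_shapes(self):
        shapes, *_ = linear_cohort(n_subjects=12, n_points=40)
        model = build_ssm(shapes)
        for s in shapes:
            assert reconstruction_residual(s, model) < 1e-6

    def test_variance_conservation(self):
        shapes, *_ = linear_cohort(n_subjects=15, n_points=30)
        model = build_ssm(shapes)
        data = np.stack([s.coordinates for s in shapes])
        total = ((data - data.mean(axis=0)) ** 2).sum() / (len(shapes) - 1)
        assert (model.mode_stddevs ** 2).sum() == pytest.approx(total,
                                                                rel=1e-6)

    def test_modes_orthonormal_and_scores_centred(self):
        shapes, *_ = linear_cohort(n_subjects=10, n_points=25)
        model = build_ssm(shapes)
        gram = model.modes @ model.modes.T
        np.testing.assert_allclose(gram, np.eye(model.n_modes), atol=1e-8)
        np.testing.assert_allclose(model.scores.mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(model.scores.std(axis=0, ddof=1),
                                   model.mode_stddevs, rtol=1e-6)

    def test_deterministic_with_positive_sign_convention(self):
        shapes, *_ = linear_cohort(n_subjects=8, n_points=20)
        m1, m2 = build_ssm(shapes), build_ssm(shapes)
        np.testing.assert_array_equal(m1.modes, m2.modes)
        for k in range(m1.n_modes):
            assert m1.modes[k, np.argmax(np.abs(m1.modes[k]))] > 0

    def test_input_validation(self):
        a = CorrespondedShape(np.zeros(30))
        with pytest.raises(ValueError):
            build_ssm([a])
        with pytest.raises(ValueError):
            build_ssm([a, CorrespondedShape(np.zeros(33))])


@pytest.fixture(scope="module")
def model():
    shapes, *_ = linear_cohort(n_subjects=20, n_points=30)
    return build_ssm(shapes)


class TestProjectAndSample:
    def test_mean_projects_to_zero(self, model):
        scores = project(CorrespondedShape(model.mean_shape), model)
        np.testing.assert_allclose(scores, 0, atol=1e-8)

    def test_mode_displacement_projects_to_its_score(self, model):
        lam = model.mode_stddevs[0]
        shape = CorrespondedShape(model.mean_shape + 2 * lam * model.modes[0])
        scores = project(shape, model)
        assert scores[0] == pytest.approx(2 * lam, abs=1e-8)
        np.testing.assert_allclose(scores[1:], 0, atol=1e-8)

    def test_sample_mode_zero_is_mean(self, model):
        out = sample_mode(model, 1, 0.0)
        np.testing.assert_allclose(out.coordinates, model.mean_shape)

    def test_sample_mode_plus_minus_average_to_mean(self, model):
        plus = sample_mode(model, 2, +2.0)
        minus = sample_mode(model, 2, -2.0)
        np.testing.assert_allclose((plus.coordinates + minus.coordinates) / 2,
                                   model.mean_shape, atol=1e-10)

    def test_sample_mode_displacement_norm(self, model):
        out = sample_mode(model, 1, +2.0)
        norm = np.linalg.norm(out.coordinates - model.mean_shape)
        assert norm == pytest.approx(2 * model.mode_stddevs[0], rel=1e-10)

    def test_sample_mode_index_bounds(self, model):
        with pytest.raises(ValueError):
            sample_mode(model, model.n_modes + 1, 1.0)

    def test_variance_explained_monotone_and_complete(self, model):
        fracs = [variance_explained(model, k)
                 for k in range(model.n_modes + 1)]
        assert fracs[0] == 0.0
        assert fracs[-1] == pytest.approx(1.0)
        assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))


def test_save_load_round_trip(tmp_path):
    shapes, *_ = linear_cohort(n_subjects=6, n_points=15)
    model = build_ssm(shapes)
    path = tmp_path / "model.json"
    model.save(path)
    back = ShapeModel.load(path)
    np.testing.assert_allclose(back.mean_shape, model.mean_shape)
    np.testing.assert_allclose(back.modes, model.modes)
    np.testing.assert_allclose(back.mode_stddevs, model.mode_stddevs)
    np.testing.assert_allclose(back.scores, model.scores)
    assert back.subject_ids == model.subject_ids


def test_procrustes_alignment_removes_rigid_pose_scatter():
    rng = np.random.default_rng(9)
    base = rng.uniform(-10, 10, (40, 3))
    shapes = []
    for i in range(6):
        r = random_rotation(rng, 15.0)
        shapes.append(CorrespondedShape.from_points(
            base @ r.T + rng.uniform(-5, 5, 3), f"s{i}"))
    aligned = procrustes_align(shapes)
    pts = [s.points for s in aligned]
    for p in pts[1:]:
        np.testing.assert_allclose(p, pts[0], atol=1e-6)
    # size untouched: centroid spread of each shape is preserved
    for before, after in zip(shapes, aligned):
        spread_b = np.linalg.norm(before.points - before.points.mean(axis=0))
        spread_a = np.linalg.norm(after.points - after.points.mean(axis=0))
        assert spread_a == pytest.approx(spread_b, rel=1e-12)
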