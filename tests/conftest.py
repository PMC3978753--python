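import numpy as np
import pytest

from meniscus_ssm.synthetic import (CohortSpec, MeniscusParams,
                                    generate_cohort, generate_meniscus)


@pytest.fixture(scope="session")
def default_mesh_truth():
    """Noise-free synthetic meniscus at default parameters + ground truth."""
    return generate_meniscus(MeniscusParams())


@pytest.fixture(scope="session")
def default_mesh(default_mesh_truth):
    return default_mesh_truth[0]


@pytest.fixture(scope="session")
def small_cohort():
    """Eight-subject cohort for fast pipeline tests."""
    return generate_cohort(CohortSpec(n_subjects=8, seed=11))


@pytest.fixture(scope="session")
def study_cohort():
    """The full-size study cohort (n = 50, balanced sexes, fixed seed)."""
    return generate_cohort(CohortSpec(n_subjects=50, seed=7))


def random_rotation(rng: np.random.Generator, max_angle_deg: float
                    ) -> np.ndarray:
    """Uniform random axis, uniform angle in (0, max_angle_deg]."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_angle_deg))
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
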