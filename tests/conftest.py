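import numpy as np
import pytest
import trimesh

from artissm import (SyntheticConfig, TriangleMesh, generate_population,
                     generate_reference_limb)


@pytest.fixture(scope="session")
def reference():
    return generate_reference_limb()


@pytest.fixture(scope="session")
def small_population(reference):
    """12 subjects, 3 latent modes, exact correspondence (no remeshing)."""
    cfg = SyntheticConfig(n_subjects=12, seed=42)
    subjects, truth = generate_population(reference, cfg)
    return subjects, truth


@pytest.fixture(scope="session")
def fitted_model(reference, small_population):
    """SSM fitted on the ground-truth normalized subjects."""
    from artissm import ArticulatedShapeModel

    _, truth = small_population
    model = ArticulatedShapeModel.from_subjects(truth.normalized_subjects, reference)
    return model.fit()


def icosphere(radius=1.0, subdivisions=2, name="sphere"):
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(m.vertices), np.asarray(m.faces), name)


@pytest.fixture
def unit_sphere():
    return icosphere(1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_rigid(rng, max_translation=50.0):
    from scipy.spatial.transform import Rotation

    from artissm import RigidTransform

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-max_translation, max_translation, 3)
    return RigidTransform.from_parts(R, t)
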