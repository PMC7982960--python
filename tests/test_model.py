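"""Shape vectors, the PCA core (Gram-matrix route vs dense-covariance
oracle), synthesis/projection identities, sampling and posed
reconstruction."""

import numpy as np
import pytest

from artissm import (ArticulatedShapeModel, LayoutError, ShapeVectorLayout,
                     articulate, assemble_shape_vector,
                     disassemble_shape_vector, sphere_exp)


class _StubLayout:
    """Minimal layout for raw-matrix PCA tests."""

    def __init__(self, size):
        self.size = size

    def geometry_block(self, v):
        return np.asarray(v)

    @property
    def geometry_size(self):
        return self.size


def dense_pca_oracle(X):
    """Reference PCA: eigendecomposition of the dense 3F x 3F sample
    covariance (divisor L-1)."""
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (len(X) - 1)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    return np.sqrt(np.clip(w[order], 0, None)), V[:, order]


class TestPCACore:
    def test_gram_route_matches_dense_covariance(self, rng):
        L, F = 10, 50
        X = rng.normal(size=(L, F))
        res = ArticulatedShapeModel(X, _StubLayout(F), {}).fit()
        sig_o, V_o = dense_pca_oracle(X)
        np.testing.assert_allclose(res.sigmas_, sig_o[:L - 1], rtol=1e-8)
        for k in range(L - 1):
            dot = abs(res.modes_[:, k] @ V_o[:, k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_identical_shapes_give_zero_variance(self, rng):
        s = rng.normal(size=30)
        res = ArticulatedShapeModel(np.tile(s, (5, 1)), _StubLayout(30), {}).fit()
        np.testing.assert_allclose(res.sigmas_, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.mean_, s, atol=1e-12)

    def test_total_variance_conserved(self, rng):
        X = rng.normal(size=(8, 40))
        res = ArticulatedShapeModel(X, _StubLayout(40), {}).fit()
        Xc = X - X.mean(axis=0)
        total = (Xc ** 2).sum() / (len(X) - 1)
        assert res.variances_.sum() == pytest.approx(total, rel=1e-8)

    def test_variances_sorted_and_modes_orthonormal(self, rng):
        X = rng.normal(size=(12, 60))
        res = ArticulatedShapeModel(X, _StubLayout(60), {}).fit()
        assert np.all(np.diff(res.sigmas_) <= 1e-12)
        np.testing.assert_allclose(res.modes_.T @ res.modes_,
                                   np.eye(res.n_modes), atol=1e-9)

    def test_exact_low_rank_population(self, reference, small_population):
        # 3 orthogonal latent modes, no noise: modes 4+ are numerically null
        _, truth = small_population
        model = ArticulatedShapeModel.from_subjects(truth.normalized_subjects, reference)
        res = model.fit()
        assert res.sigmas_[3] < 1e-7 * res.sigmas_[0]


class TestSynthesisProjection:
    def test_zero_weights_give_mean(self, rng):
        X = rng.normal(size=(6, 20))
        res = ArticulatedShapeModel(X, _StubLayout(20), {}).fit()
        np.testing.assert_allclose(res.synthesize(np.zeros(5)), res.mean_, atol=1e-12)

    def test_unit_mode_displacement(self, rng):
        X = rng.normal(size=(6, 20))
        res = ArticulatedShapeModel(X, _StubLayout(20), {}).fit()
        e1 = np.zeros(res.n_modes)
        e1[0] = 1.0
        s = res.synthesize(e1)
        assert np.linalg.norm(s - res.mean_) == pytest.approx(res.sigmas_[0], rel=1e-10)

    def test_projection_identity_on_training_shapes(self, rng):
        X = rng.normal(size=(8, 30))
        res = ArticulatedShapeModel(X, _StubLayout(30), {}).fit()
        for s in X:  # training data lie in the span of all L-1 modes
            recon = res.synthesize(res.project(s))
            assert np.sqrt(((recon - s) ** 2).mean()) < 1e-9

    def test_fit_synthesize_weight_identity(self, rng):
        X = rng.normal(size=(8, 30))
        res = ArticulatedShapeModel(X, _StubLayout(30), {}).fit()
        for _ in range(10):
            b = rng.normal(size=res.n_modes)
            np.testing.assert_allclose(res.project(res.synthesize(b)), b, atol=1e-9)

    def test_constructed_weight(self, rng):
        X = rng.normal(size=(8, 30))
        res = ArticulatedShapeModel(X, _StubLayout(30), {}).fit()
        s = res.mean_ + 2.0 * res.sigmas_[2] * res.modes_[:, 2]
        b = res.project(s)
        expected = np.zeros(res.n_modes)
        expected[2] = 2.0
        np.testing.assert_allclose(b, expected, atol=1e-9)

    def test_residual_orthogonal_to_modes(self, rng):
        X = rng.normal(size=(6, 40))
        res = ArticulatedShapeModel(X, _StubLayout(40), {}).fit()
        s = rng.normal(size=40)
        b = res.project(s)
        resid = (s - res.mean_) - res.modes_ @ (res.sigmas_ * b)
        np.testing.assert_allclose(res.modes_.T @ resid, 0.0, atol=1e-9)


class TestSampling:
    def test_seed_determinism(self, fitted_model):
        v1, w1 = fitted_model.sample(5, seed=9)
        v2, w2 = fitted_model.sample(5, seed=9)
        np.testing.assert_array_equal(v1, v2)
        np.testing.assert_array_equal(w1, w2)

    def test_mode_variances_match_sigmas(self, rng):
        X = rng.normal(size=(10, 25))
        res = ArticulatedShapeModel(X, _StubLayout(25), {}).fit()
        vectors, _ = res.sample(10000, seed=1)
        coeffs = (vectors - res.mean_) @ res.modes_
        sample_sd = coeffs.std(axis=0, ddof=1)
        np.testing.assert_allclose(sample_sd[:3], res.sigmas_[:3], rtol=0.05)

    def test_zero_variance_model_samples_mean(self, rng):
        s = rng.normal(size=30)
        res = ArticulatedShapeModel(np.tile(s, (4, 1)), _StubLayout(30), {}).fit()
        vectors, _ = res.sample(7, seed=0)
        np.testing.assert_allclose(vectors, np.tile(s, (7, 1)), atol=1e-12)


class TestShapeVectors:
    def test_round_trip(self, reference, fitted_model):
        layout = fitted_model.layout
        mus = fitted_model.mus
        s = assemble_shape_vector(reference, layout, mus)
        limb = disassemble_shape_vector(s, layout, mus)
        s2 = assemble_shape_vector(limb, layout, mus)
        np.testing.assert_allclose(s2, s, atol=1e-9)

    def test_vector_length_formula(self, reference):
        layout = ShapeVectorLayout(reference)
        total_vertices = reference.total_vertices()
        assert layout.size == 3 * (total_vertices + 2 * 4)

    def test_axis_block_zero_at_intrinsic_mean(self, reference):
        layout = ShapeVectorLayout(reference)
        mus = {bid: reference.skeleton.bones[bid].z_axis.copy()
               for bid in layout.bone_order}
        s = assemble_shape_vector(reference, layout, mus)
        for bid in layout.bone_order:
            np.testing.assert_allclose(s[layout.axis_slice(bid)], 0.0, atol=1e-12)

    def test_wrong_length_rejected(self, reference):
        layout = ShapeVectorLayout(reference)
        mus = {bid: reference.skeleton.bones[bid].z_axis for bid in layout.bone_order}
        with pytest.raises(LayoutError):
            disassemble_shape_vector(np.zeros(layout.size + 1), layout, mus)


class TestPosedReconstruction:
    ANGLES = {"MCP": 0.2, "PIP": 0.1, "DIP": -0.15}

    def test_mean_at_zero(self, fitted_model):
        limb = fitted_model.reconstruct_posed(np.zeros(fitted_model.n_modes),
                                              {"MCP": 0.0, "PIP": 0.0, "DIP": 0.0})
        mean_limb = fitted_model.instance(np.zeros(fitted_model.n_modes))
        for c in limb.components:
            np.testing.assert_allclose(limb.components[c].vertices,
                                       mean_limb.components[c].vertices, atol=1e-9)

    def test_continuity_in_angle(self, fitted_model, rng):
        b = rng.normal(size=3)
        base = fitted_model.reconstruct_posed(b, {"MCP": 0.0})
        for eps in (1e-3, 1e-5):
            moved = fitted_model.reconstruct_posed(b, {"MCP": eps})
            disp = max(np.abs(moved.components[c].vertices
                              - base.components[c].vertices).max()
                       for c in base.components)
            assert disp < 300 * eps

    def test_commutes_with_articulation(self, reference, small_population, fitted_model):
        # reconstructing a training subject posed equals articulating the
        # subject's latent (pose-free) shape
        _, truth = small_population
        shape = truth.normalized_subjects[0]
        s = assemble_shape_vector(shape, fitted_model.layout, fitted_model.mus)
        b = fitted_model.project(s)
        posed = fitted_model.reconstruct_posed(b, self.ANGLES)
        expected = articulate(shape, self.ANGLES)
        for c in expected.components:
            np.testing.assert_allclose(posed.components[c].vertices,
                                       expected.components[c].vertices, atol=1e-6)

    def test_archive_round_trip(self, fitted_model, tmp_path):
        from artissm import ShapeModelResults

        d = str(tmp_path / "ssm")
        fitted_model.save(d)
        back = ShapeModelResults.load(d)
        np.testing.assert_allclose(back.mean_, fitted_model.mean_, atol=1e-12)
        np.testing.assert_allclose(back.modes_, fitted_model.modes_, atol=1e-12)
        np.testing.assert_allclose(back.sigmas_, fitted_model.sigmas_, atol=1e-12)
        limb = back.instance(np.array([1.0, 0, 0]))
        assert set(limb.components) == set(fitted_model.layout.component_order)

    def test_summary_mentions_modes(self, fitted_model):
        text = fitted_model.summary()
        assert "retained modes" in text and "cum %" in text
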