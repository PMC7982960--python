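"""Biometric measurements, their invariances, the weight regression and
the linearity confidence-interval machinery."""

import numpy as np
import pytest

from artissm import (BIOMETRIC_IDS, RigidTransform, SchemaError,
                     assemble_shape_vector, biometric_ci, compute_biometric,
                     correlation_table, fit_biometric_regression,
                     generate_reference_limb, instance_from_biometric)
from .conftest import random_rigid


class TestComputeBiometric:
    def test_all_ids_finite_on_reference(self, reference):
        for bid in BIOMETRIC_IDS:
            v = compute_biometric(reference, reference.landmarks, bid)
            assert np.isfinite(v), bid

    def test_toe_angle_matches_construction(self):
        for ta in (45.0, 50.0, 55.0):
            limb = generate_reference_limb(toe_angle_deg=ta)
            assert compute_biometric(limb, limb.landmarks, "TA") == pytest.approx(ta, abs=0.5)

    def test_heel_and_coffin_angles_match_construction(self):
        limb = generate_reference_limb(heel_angle_deg=38.0, coffin_angle_deg=52.0)
        assert compute_biometric(limb, limb.landmarks, "HA") == pytest.approx(38.0, abs=0.5)
        assert compute_biometric(limb, limb.landmarks, "CA") == pytest.approx(52.0, abs=0.5)

    def test_underrun_is_heel_minus_toe(self, reference):
        s = reference.landmarks
        ur = compute_biometric(reference, s, "UR")
        ha = compute_biometric(reference, s, "HA")
        ta = compute_biometric(reference, s, "TA")
        assert ur == pytest.approx(ha - ta, abs=1e-12)

    def test_capsule_deviation_is_coffin_minus_toe(self, reference):
        s = reference.landmarks
        assert compute_biometric(reference, s, "CD") == pytest.approx(
            compute_biometric(reference, s, "CA")
            - compute_biometric(reference, s, "TA"), abs=1e-12)

    def test_joint_radii_match_construction(self, reference):
        s = reference.landmarks
        assert compute_biometric(reference, s, "CR_MC3") == pytest.approx(12.0, rel=0.01)
        assert compute_biometric(reference, s, "CR_P1") == pytest.approx(10.0, rel=0.01)
        assert compute_biometric(reference, s, "CR_P2") == pytest.approx(8.0, rel=0.01)

    LENGTH_IDS = [b for b, u in
                  __import__("artissm").biometrics.UNITS.items() if u == "mm"]
    ANGLE_IDS = [b for b, u in
                 __import__("artissm").biometrics.UNITS.items() if u == "deg"]

    def test_similarity_invariance(self, reference):
        scaled = reference.transformed(
            RigidTransform.from_parts(np.eye(3), np.zeros(3), 2.0))
        s = reference.landmarks
        for bid in self.LENGTH_IDS:
            assert compute_biometric(scaled, s, bid) == pytest.approx(
                2.0 * compute_biometric(reference, s, bid), rel=1e-6), bid
        for bid in self.ANGLE_IDS + ["TS"]:
            assert compute_biometric(scaled, s, bid) == pytest.approx(
                compute_biometric(reference, s, bid), abs=1e-6), bid

    def test_rigid_motion_invariance(self, reference, rng):
        moved = reference.transformed(random_rigid(rng))
        s = reference.landmarks
        for bid in BIOMETRIC_IDS:
            assert compute_biometric(moved, s, bid) == pytest.approx(
                compute_biometric(reference, s, bid), abs=1e-6), bid

    def test_missing_landmark_names_biometric(self, reference):
        from artissm import LandmarkSchema

        empty = LandmarkSchema()
        with pytest.raises(SchemaError, match="TA"):
            compute_biometric(reference, empty, "TA")

    def test_unknown_id_rejected(self, reference):
        with pytest.raises(KeyError):
            compute_biometric(reference, reference.landmarks, "XX")


def linear_biometric(results, direction=0, offset=5.0, scale=1.0):
    """A biometric that is an exact affine functional of the mode weights."""
    layout, mus = results.layout, results.mus
    u = results.modes_[:, direction]
    sd = results.sigmas_[direction]

    def fn(limb):
        s = assemble_shape_vector(limb, layout, mus)
        return offset + scale * (u @ (s - results.mean_)) / sd

    fn.__name__ = "linear_fixture"
    return fn


def quadratic_biometric(results, curvature=0.15):
    layout, mus = results.layout, results.mus
    u = results.modes_[:, 0]
    sd = results.sigmas_[0]

    def fn(limb):
        s = assemble_shape_vector(limb, layout, mus)
        b1 = (u @ (s - results.mean_)) / sd
        return 5.0 + b1 + curvature * b1 ** 2

    fn.__name__ = "quadratic_fixture"
    return fn


class TestRegression:
    def test_linear_functional_recovered(self, fitted_model, reference):
        fn = linear_biometric(fitted_model)
        reg = fit_biometric_regression(fitted_model, reference.landmarks, fn,
                                       n=200, seed=0)
        # the slope along mode 1 is exactly 1 (in-sample least squares on
        # k = 5 + b1); other slopes are only sampling noise ~ 1/sqrt(n)
        assert reg.beta[0] == pytest.approx(1.0, abs=1e-9)
        assert np.abs(reg.beta[1:]).max() < 3 / np.sqrt(200)
        # the mode-1 coordinate of b(k) reproduces k exactly
        b_at = instance_from_biometric(reg, 6.3)
        assert reg.alpha[0] + reg.beta[0] * 6.3 == pytest.approx(b_at[0])
        assert b_at[0] == pytest.approx(6.3 - 5.0, abs=1e-9)

    def test_seed_determinism(self, fitted_model, reference):
        kw = dict(n=100, seed=3)
        r1 = fit_biometric_regression(fitted_model, reference.landmarks, "TA", **kw)
        r2 = fit_biometric_regression(fitted_model, reference.landmarks, "TA", **kw)
        np.testing.assert_array_equal(r1.alpha, r2.alpha)
        np.testing.assert_array_equal(r1.beta, r2.beta)

    def test_slope_stability_with_sample_size(self, fitted_model, reference):
        fn = linear_biometric(fitted_model)
        r1 = fit_biometric_regression(fitted_model, reference.landmarks, fn, n=300, seed=1)
        r2 = fit_biometric_regression(fitted_model, reference.landmarks, fn, n=1200, seed=2)
        assert r1.beta[0] == pytest.approx(r2.beta[0], rel=0.05)

    def test_morph_symmetry(self, fitted_model, reference):
        reg = fit_biometric_regression(fitted_model, reference.landmarks, "TA",
                                       n=150, seed=0)
        lo = instance_from_biometric(reg, reg.mean_k - 3 * reg.sd_k)
        hi = instance_from_biometric(reg, reg.mean_k + 3 * reg.sd_k)
        mid = instance_from_biometric(reg, reg.mean_k)
        np.testing.assert_allclose(0.5 * (lo + hi), mid, atol=1e-9)


class TestLinearityCI:
    def test_linear_fixture_has_zero_width(self, fitted_model, reference):
        fn = linear_biometric(fitted_model)
        reg = fit_biometric_regression(fitted_model, reference.landmarks, fn,
                                       n=200, seed=0)
        ci = biometric_ci(fitted_model, reference.landmarks, reg, fn, grid=9)
        assert abs(ci.ci_min) < 1e-6 and abs(ci.ci_max) < 1e-6

    def test_quadratic_fixture_strictly_wider(self, fitted_model, reference):
        fn_l = linear_biometric(fitted_model)
        fn_q = quadratic_biometric(fitted_model)
        reg_l = fit_biometric_regression(fitted_model, reference.landmarks, fn_l,
                                         n=200, seed=0)
        reg_q = fit_biometric_regression(fitted_model, reference.landmarks, fn_q,
                                         n=200, seed=0)
        ci_l = biometric_ci(fitted_model, reference.landmarks, reg_l, fn_l, grid=9)
        ci_q = biometric_ci(fitted_model, reference.landmarks, reg_q, fn_q, grid=9)
        width_l = ci_l.ci_max - ci_l.ci_min
        width_q = ci_q.ci_max - ci_q.ci_min
        assert width_q > 10 * width_l

    def test_interval_brackets_zero_for_linear(self, fitted_model, reference):
        fn = linear_biometric(fitted_model)
        reg = fit_biometric_regression(fitted_model, reference.landmarks, fn,
                                       n=200, seed=0)
        ci = biometric_ci(fitted_model, reference.landmarks, reg, fn, grid=9)
        assert ci.ci_min <= 0 <= ci.ci_max or abs(ci.ci_min) < 1e-6


class TestCorrelationTable:
    def test_unit_diagonal_and_symmetry(self, fitted_model, reference):
        tab = correlation_table(fitted_model, reference.landmarks,
                                ["TA", "HA", "UR"], n=60, seed=0)
        np.testing.assert_allclose(np.diag(tab.values), 1.0, atol=1e-12)
        np.testing.assert_allclose(tab.values, tab.values.T, atol=1e-12)

    def test_underrun_identity(self, fitted_model, reference):
        # corr(UR, HA) must equal corr(HA - TA, HA) computed by hand
        from artissm.biometrics import _sampled_biometrics

        _, vals, _ = _sampled_biometrics(fitted_model, reference.landmarks,
                                         ["TA", "HA", "UR"], 60, 0)
        tab = correlation_table(fitted_model, reference.landmarks,
                                ["TA", "HA", "UR"], n=60, seed=0)
        manual = np.corrcoef(vals["HA"] - vals["TA"], vals["HA"])[0, 1]
        assert tab.loc["UR", "HA"] == pytest.approx(manual, abs=1e-9)

    def test_independent_fixtures_uncorrelated(self, fitted_model, reference):
        fa = linear_biometric(fitted_model, direction=0)
        fb = linear_biometric(fitted_model, direction=1)
        fb.__name__ = "linear_fixture_2"
        n = 400
        tab = correlation_table(fitted_model, reference.landmarks, [fa, fb],
                                n=n, seed=0)
        assert abs(tab.iloc[0, 1]) < 3 / np.sqrt(n)
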