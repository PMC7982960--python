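"""Rigid pre-alignment, elastic registration and the two-pass
correspondence builder (small fixtures; the full remeshed-population run
lives in the acceptance suite)."""

import numpy as np
import pytest

from artissm import (RegistrationParams, RigidTransform, apply_transform,
                     build_correspondences, elastic_register,
                     registration_report, rigid_prealign,
                     signed_geometric_error)
from artissm.registration import correspondence_from_matched
from .conftest import random_rigid


@pytest.fixture(scope="module")
def capsule(reference):
    return reference.components["capsule"]


class TestRigidPrealign:
    def test_identity_for_identical_meshes(self, capsule):
        res = rigid_prealign(capsule, capsule)
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(res.transform.translation_vector, 0.0, atol=1e-4)
        assert res.residual < 1e-6

    def test_recovers_known_motion(self, capsule, rng):
        for _ in range(3):
            t_true = random_rigid(rng, max_translation=30.0)
            target = apply_transform(capsule, t_true)
            res = rigid_prealign(capsule, target)
            np.testing.assert_allclose(res.transform.rotation, t_true.rotation, atol=1e-4)
            np.testing.assert_allclose(res.transform.translation_vector,
                                       t_true.translation_vector, atol=1e-3)

    def test_recovers_known_similarity(self, capsule, rng):
        s = 1.15
        t_true = random_rigid(rng, max_translation=20.0)
        scaled = capsule.with_vertices(capsule.vertices * s)
        target = apply_transform(scaled, t_true)
        res = rigid_prealign(capsule, target)
        # point-to-facet matching shrinks the scale slightly (chord bias):
        # the pre-alignment contract is percent-level scale accuracy
        assert res.transform.scale == pytest.approx(s, abs=5e-3)

    def test_flip_hypotheses_beat_any_single_start(self, capsule, rng):
        # the kept hypothesis must be at least as good as each single
        # principal-axes start refined the same way
        from artissm.distance import SurfaceQuery
        from artissm.registration import _principal_frame, _run_icp

        t_true = random_rigid(rng)
        target = apply_transform(capsule, t_true)
        best = rigid_prealign(capsule, target)
        query = SurfaceQuery(target)
        c_r, V_r = _principal_frame(capsule.vertices)
        c_t, V_t = _principal_frame(target.vertices)
        for f in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]):
            R0 = V_t @ np.diag(f) @ V_r.T
            *_, rms, _ = _run_icp(capsule.vertices, query, R0, c_t - R0 @ c_r,
                                  1.0, True, 35, 1e-7)
            assert best.residual <= rms + 1e-6

    def test_converged_flag_reported(self, capsule):
        params = RegistrationParams(icp_iterations=1)
        res = rigid_prealign(capsule, capsule, params)
        assert isinstance(res.converged, bool)


class TestElasticRegister:
    def test_fixed_point_on_identical_target(self, capsule):
        out = elastic_register(capsule, capsule)
        np.testing.assert_allclose(out.vertices, capsule.vertices, atol=1e-3)
        np.testing.assert_array_equal(out.faces, capsule.faces)

    def test_tracks_smooth_bump(self, reference):
        # radial bump of 2 mm amplitude on P2; topology identical but the
        # registration must rediscover the deformation from geometry alone
        p2 = reference.components["P2"]
        center = p2.centroid()
        rel = p2.vertices - center
        r = np.linalg.norm(rel, axis=1, keepdims=True)
        bump = 2.0 * np.exp(-((p2.vertices[:, 1:2] - center[1]) / 6.0) ** 2)
        target = p2.with_vertices(p2.vertices + bump * rel / r)
        out, trace = elastic_register(p2, target, force=True, return_trace=True)
        err = signed_geometric_error(out, target)
        assert err.mean_unsigned < 0.1

    def test_error_decreases_over_schedule(self, reference):
        p2 = reference.components["P2"]
        target = p2.with_vertices(p2.vertices * 1.04 + np.array([0.5, 0, 0]))
        _, trace = elastic_register(p2, target, force=True, return_trace=True)
        assert all(b <= a + 1e-6 for a, b in zip(trace, trace[1:]))

    def test_displacement_field_is_smooth(self, reference):
        p2 = reference.components["P2"]
        center = p2.centroid()
        rel = p2.vertices - center
        r = np.linalg.norm(rel, axis=1, keepdims=True)
        bump = 2.0 * np.exp(-((p2.vertices[:, 1:2] - center[1]) / 6.0) ** 2)
        target = p2.with_vertices(p2.vertices + bump * rel / r)
        out = elastic_register(p2, target, force=True)
        disp = out.vertices - p2.vertices
        edges = p2.edges()
        edge_jump = np.linalg.norm(disp[edges[:, 0]] - disp[edges[:, 1]], axis=1)
        assert edge_jump.max() < 1.5  # smooth relative to the 2 mm bump

    def test_small_target_refused_without_force(self, reference):
        small = reference.components["DS"]  # 42 vertices
        with pytest.raises(ValueError, match="under-constrained"):
            elastic_register(small, small)


class TestCorrespondences:
    def test_identical_subjects_fixed_point(self, reference):
        subs = []
        for k in range(3):
            m = reference.copy()
            m.name = f"s{k}"
            subs.append(m)
        cs = build_correspondences(reference, subs, two_pass=True)
        cs.check_topology()
        for sc in cs.subjects:
            for comp in reference.components:
                err = np.abs(sc.meshes[comp].vertices
                             - reference.components[comp].vertices).max()
                assert err < 0.05
        # pass-2 reference is the mean, which equals the common subject
        for comp in reference.components:
            np.testing.assert_allclose(cs.reference.components[comp].vertices,
                                       reference.components[comp].vertices, atol=0.05)

    def test_missing_component_skips_subject(self, reference):
        good = reference.copy()
        good.name = "good"
        bad = reference.copy()
        bad.name = "bad"
        del bad.components["DS"]
        del bad.skeleton.component_to_bone["DS"]
        cs = build_correspondences(reference, [good, bad], two_pass=False)
        assert cs.skipped == ["bad"]
        assert [s.name for s in cs.subjects] == ["good"]

    def test_matched_route_requires_topology(self, reference):
        other = reference.copy()
        other.components["DS"] = other.components["DS"].with_vertices(
            other.components["DS"].vertices)
        other.components["DS"].faces = other.components["DS"].faces[:-1]
        cs = correspondence_from_matched(reference, [other])  # faces may differ
        bad = reference.copy()
        bad.components["DS"] = reference.components["P2"].copy()
        with pytest.raises(ValueError, match="topology"):
            correspondence_from_matched(reference, [bad])


class TestTwoPassOnRemeshedPopulation:
    def test_second_pass_does_not_degrade_error(self, reference):
        from artissm import SyntheticConfig, generate_population

        cfg = SyntheticConfig(n_subjects=3, seed=13, remesh=True)
        subjects, _ = generate_population(reference, cfg)
        one = build_correspondences(reference, subjects, two_pass=False)
        two = build_correspondences(reference, subjects, two_pass=True)
        err1 = registration_report(one, subjects).global_mean_unsigned
        err2 = registration_report(two, subjects).global_mean_unsigned
        assert err2 <= 1.05 * err1 + 1e-6
        two.check_topology()


class TestRegistrationReport:
    def test_perfect_registration_zero_errors(self, reference):
        subj = reference.copy()
        subj.name = "s0"
        cs = correspondence_from_matched(reference, [subj])
        rep = registration_report(cs, [subj])
        assert rep.global_mean_unsigned == pytest.approx(0.0, abs=1e-12)
        assert rep.global_sd_unsigned == 0.0
        for comp in reference.components:
            np.testing.assert_allclose(rep.per_vertex_sd[comp], 0.0)

    def test_single_subject_sd_zero(self, reference, rng):
        subj = reference.copy()
        subj.name = "s0"
        noisy = {c: m.with_vertices(m.vertices + rng.normal(0, 0.1, m.vertices.shape))
                 for c, m in reference.components.items()}
        cs = correspondence_from_matched(reference, [subj])
        cs.subjects[0].meshes = {c: m.copy() for c, m in noisy.items()}
        rep = registration_report(cs, [subj])
        for comp in reference.components:
            np.testing.assert_allclose(rep.per_vertex_sd[comp], 0.0)
        assert rep.global_mean_unsigned > 0

    def test_global_mean_matches_direct_recomputation(self, reference, rng):
        subj = reference.copy()
        subj.name = "s0"
        cs = correspondence_from_matched(reference, [subj])
        moved = {c: m.with_vertices(m.vertices + rng.normal(0, 0.2, m.vertices.shape))
                 for c, m in reference.components.items()}
        cs.subjects[0].meshes = moved
        rep = registration_report(cs, [subj])
        direct = np.concatenate([
            np.abs(signed_geometric_error(moved[c], subj.components[c]).distances)
            for c in reference.components])
        assert rep.global_mean_unsigned == pytest.approx(direct.mean(), rel=1e-9)
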