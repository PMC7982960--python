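"""Scale and pose normalization of registered subjects.

Global scale is removed by matching the subject's third-metacarpal length
(extent along the bone frame's y-axis) to the reference's.  Acquisition
pose is removed by aligning the root (metacarpal group) with the
reference through its pre-alignment transform and then, proximal to
distal, rotating each bone about its flexion axis by the optimal flexion
angle

    theta* = argmin_theta || ref_local - Rz(theta) subj_local ||^2

solved in closed form (single-axis Procrustes).  Only flexion/extension is
optimized; abduction/adduction and internal rotation are left in the data
as remnant posture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .limb import LimbModel
from .mesh import RigidTransform, TriangleMesh
from .skeleton import BoneFrame, Skeleton, flexion_transform


class UndefinedAngleError(ValueError):
    """All points on the rotation axis: flexion angle undetermined."""


def optimal_flexion(reference_local: np.ndarray, subject_local: np.ndarray) -> float:
    """Closed-form optimal rotation angle about the local z-axis.

    Minimizes ||a - Rz(theta) b||^2 over theta for corresponding point sets
    a (reference) and b (subject), both expressed in the parent-bone local
    frame: theta* = atan2(sum (b x a) . z, sum (a.b - a_z b_z)).
    """
    a = np.asarray(reference_local, float)
    b = np.asarray(subject_local, float)
    if a.shape != b.shape:
        raise ValueError("corresponding point sets must have equal shapes")
    C = float(np.einsum("ij,ij->", a[:, :2], b[:, :2]))
    S = float(np.einsum("i,i->", a[:, 1], b[:, 0]) - np.einsum("i,i->", a[:, 0], b[:, 1]))
    if abs(C) < 1e-30 and abs(S) < 1e-30:
        raise UndefinedAngleError("all points lie on the rotation axis")
    return float(np.arctan2(S, C))


@dataclass
class NormalizedSubject:
    """A subject in the reference's scale- and pose-normalized frame."""

    name: str
    components: dict[str, TriangleMesh]
    thetas: dict[str, float]          # applied flexion corrections, radians
    scale_factor: float
    skeleton: Skeleton                # estimated subject skeleton, normalized coords

    def to_limb_model(self, reference: LimbModel) -> LimbModel:
        return LimbModel({k: m.copy() for k, m in self.components.items()},
                         self.skeleton.copy(), reference.landmarks,
                         {b: (c, i.copy()) for b, (c, i) in reference.joint_surfaces.items()},
                         self.name)


def _mc3_length(vertices: np.ndarray, y_axis: np.ndarray) -> float:
    proj = vertices @ y_axis
    length = float(proj.max() - proj.min())
    if length <= 0:
        raise ValueError("computed a non-positive third-metacarpal length")
    return length


def scale_normalize(sc, reference: LimbModel):
    """Scale a correspondence entry so its MC3 length matches the
    reference's.  Returns (scaled entry, factor)."""
    root_id = reference.skeleton.root_id
    root_frame = reference.skeleton.bones[root_id]
    ref_len = _mc3_length(reference.components["MC3"].vertices, root_frame.y_axis)
    t_root = sc.transforms["MC3"]
    y_subj = t_root.rotation @ root_frame.y_axis
    subj_len = _mc3_length(sc.meshes["MC3"].vertices, y_subj)
    factor = ref_len / subj_len

    from .registration import SubjectCorrespondence  # dataclass only
    scaled_meshes = {c: m.with_vertices(m.vertices * factor) for c, m in sc.meshes.items()}
    scaled_T = {}
    for c, t in sc.transforms.items():
        m = t.matrix.copy()
        m[:3] *= factor  # uniform scale about the origin composed on the left
        scaled_T[c] = RigidTransform(m, allow_scale=True)
    return SubjectCorrespondence(sc.name, scaled_meshes, scaled_T,
                                 sc.mean_unsigned_error), factor


def _estimate_bone_rotation(ref_pts: np.ndarray, subj_pts: np.ndarray) -> np.ndarray:
    """Least-squares rotation taking centered reference bone geometry onto
    the subject's (Kabsch); captures the subject's remnant orientation."""
    A = (subj_pts - subj_pts.mean(0)).T @ (ref_pts - ref_pts.mean(0))
    U, _, Vt = np.linalg.svd(A)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


def pose_normalize(sc, reference: LimbModel, factor: float = 1.0) -> NormalizedSubject:
    """Remove acquisition pose from a (scale-normalized) correspondence
    entry: root aligned via its pre-alignment transform, then optimal
    flexion applied per joint, proximal to distal.

    The returned subject carries an estimated skeleton: joint centres from
    circle fits on its own articular patches, bone frames from per-bone
    least-squares rotations relative to the reference (so remnant abduction
    and axis-direction variation stay measurable in the output).
    """
    skel = reference.skeleton
    root_id = skel.root_id
    t_root_inv = sc.transforms["MC3"].inverse()
    current = {c: t_root_inv.apply_points(m.vertices) for c, m in sc.meshes.items()}

    thetas: dict[str, float] = {}
    for bid in skel.topological_order():
        bone = skel.bones[bid]
        if bone.parent_id is None:
            continue
        T_j = skel.joint_transform(bid)
        T_j_inv = T_j.inverse()
        comps = skel.components_of(bid)
        a_loc = np.vstack([T_j_inv.apply_points(reference.components[c].vertices)
                           for c in comps])
        b_loc = np.vstack([T_j_inv.apply_points(current[c]) for c in comps])
        theta = optimal_flexion(a_loc, b_loc)
        A = flexion_transform(T_j, theta)
        for did in skel.descendants(bid):
            for c in skel.components_of(did):
                current[c] = A.apply_points(current[c])
        thetas[bone.joint_name] = theta

    meshes = {c: reference.components[c].with_vertices(v) for c, v in current.items()}

    # estimated subject skeleton in the normalized frame
    bone_R = {}
    for bid in skel.topological_order():
        comps = skel.components_of(bid)
        ref_pts = np.vstack([reference.components[c].vertices for c in comps])
        subj_pts = np.vstack([current[c] for c in comps])
        bone_R[bid] = _estimate_bone_rotation(ref_pts, subj_pts)
    bones = {}
    for bid in skel.topological_order():
        b = skel.bones[bid]
        R = bone_R[bid]
        if bid in reference.joint_surfaces:
            # transport the reference joint centre with the mean
            # correspondence displacement of its articular patch (a linear,
            # well-conditioned estimate; re-fitting the joint circle per
            # subject amplifies patch deformation into centre jitter)
            comp, idx = reference.joint_surfaces[bid]
            shift = (current[comp][idx] - reference.components[comp].vertices[idx]).mean(axis=0)
            center = b.origin + shift
        else:
            center = b.origin.copy()
        bones[bid] = BoneFrame(bid, R @ b.x_axis, R @ b.y_axis, R @ b.z_axis,
                               center, b.parent_id, b.joint_name)
    est_skel = Skeleton(bones, dict(skel.component_to_bone))
    return NormalizedSubject(sc.name, meshes, thetas, factor, est_skel)


def normalize_subject(sc, reference: LimbModel) -> NormalizedSubject:
    """scale_normalize followed by pose_normalize."""
    scaled, factor = scale_normalize(sc, reference)
    return pose_normalize(scaled, reference, factor)
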