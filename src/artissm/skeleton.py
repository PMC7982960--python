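"""Kinematic skeleton of the distal limb.

Four skeleton bones move the ten surface components: the metacarpus (MC2,
MC3, MC4 rigidly attached — the root), the proximal phalanx group (P1 plus
both proximal sesamoids), the middle phalanx (P2), and the distal group (P3,
distal sesamoid and hoof capsule).  Each bone carries an orthonormal frame
whose y-axis is the bone's elongation axis and whose z-axis is perpendicular
to the bone's sagittal plane; flexion/extension of a bone happens about its
rotation axis a_b, which is parallel to the *parent* bone's z-axis and
passes through the bone's joint centre c_b (the centre of a circle fitted to
the articular surface in the sagittal plane).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .mesh import RigidTransform


class DegeneratePoseError(ValueError):
    """Spherical-angle decomposition is singular (bone y parallel parent z)."""


class DegenerateFitError(ValueError):
    """Circle fit is under-determined (collinear projected points)."""


@dataclass
class BoneFrame:
    """Orthonormal right-handed local frame of one skeleton bone.

    ``origin`` is the bone's joint centre: the centre of the circle fitted
    to its proximal articular surface (for the root bone, a reference point
    on the bone).  ``joint_name`` labels the joint at which the bone
    articulates relative to its parent (e.g. ``"MCP"``); None for the root.
    """

    bone_id: str
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    origin: np.ndarray
    parent_id: str | None = None
    joint_name: str | None = None

    def __post_init__(self) -> None:
        for attr in ("x_axis", "y_axis", "z_axis", "origin"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=np.float64))
        R = self.rotation_matrix
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise ValueError(f"frame of bone {self.bone_id!r} is not orthonormal")
        if np.linalg.norm(np.cross(self.x_axis, self.y_axis) - self.z_axis) > 1e-6:
            raise ValueError(f"frame of bone {self.bone_id!r} is not right-handed")

    @property
    def rotation_matrix(self) -> np.ndarray:
        """Columns are (x, y, z): maps local coordinates to world directions."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    def local_to_world(self) -> RigidTransform:
        return RigidTransform.from_parts(self.rotation_matrix, self.origin)

    def transformed(self, t: RigidTransform) -> "BoneFrame":
        R = t.rotation
        return BoneFrame(
            self.bone_id,
            R @ self.x_axis, R @ self.y_axis, R @ self.z_axis,
            t.apply_points(self.origin),
            self.parent_id, self.joint_name,
        )

    def copy(self) -> "BoneFrame":
        return BoneFrame(self.bone_id, self.x_axis.copy(), self.y_axis.copy(),
                         self.z_axis.copy(), self.origin.copy(),
                         self.parent_id, self.joint_name)


@dataclass
class Skeleton:
    """Chain of bone frames plus the component-to-bone rigid grouping."""

    bones: dict[str, BoneFrame]
    component_to_bone: dict[str, str]

    def __post_init__(self) -> None:
        roots = [b for b in self.bones.values() if b.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"skeleton must have exactly one root bone, found {len(roots)}")
        for b in self.bones.values():
            if b.parent_id is not None and b.parent_id not in self.bones:
                raise ValueError(f"unknown parent {b.parent_id!r} of bone {b.bone_id!r}")
        # acyclicity: walking to the root must terminate
        for b in self.bones.values():
            seen = set()
            cur = b
            while cur.parent_id is not None:
                if cur.bone_id in seen:
                    raise ValueError("cycle in skeleton parent map")
                seen.add(cur.bone_id)
                cur = self.bones[cur.parent_id]
        for comp, bid in self.component_to_bone.items():
            if bid not in self.bones:
                raise ValueError(f"component {comp!r} mapped to unknown bone {bid!r}")

    @property
    def root_id(self) -> str:
        return next(b.bone_id for b in self.bones.values() if b.parent_id is None)

    def topological_order(self) -> list[str]:
        """Bone ids, proximal (root) first."""
        order: list[str] = []
        remaining = dict(self.bones)
        placed = set()
        while remaining:
            for bid, b in list(remaining.items()):
                if b.parent_id is None or b.parent_id in placed:
                    order.append(bid)
                    placed.add(bid)
                    del remaining[bid]
        return order

    def joint_to_bone(self) -> dict[str, str]:
        return {b.joint_name: b.bone_id for b in self.bones.values() if b.joint_name}

    def descendants(self, bone_id: str) -> list[str]:
        """bone_id plus all bones distal to it (topological order)."""
        out = []
        for bid in self.topological_order():
            b = self.bones[bid]
            if bid == bone_id or b.parent_id in out:
                out.append(bid)
        return out

    def components_of(self, bone_id: str) -> list[str]:
        return [c for c, bid in self.component_to_bone.items() if bid == bone_id]

    def joint_transform(self, bone_id: str) -> RigidTransform:
        """Local-to-world frame of bone ``bone_id``'s flexion axis: rotation
        from the parent bone's axes (so local z is the flexion axis a_b),
        translated to the bone's joint centre c_b."""
        b = self.bones[bone_id]
        if b.parent_id is None:
            raise ValueError(f"root bone {bone_id!r} has no flexion joint")
        parent = self.bones[b.parent_id]
        return RigidTransform.from_parts(parent.rotation_matrix, b.origin)

    def flexion_axis(self, bone_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(direction a_b, point c_b) of the bone's flexion axis."""
        b = self.bones[bone_id]
        parent = self.bones[b.parent_id]
        return parent.z_axis.copy(), b.origin.copy()

    def copy(self) -> "Skeleton":
        return Skeleton({k: v.copy() for k, v in self.bones.items()},
                        dict(self.component_to_bone))


# ----------------------------------------------------------------------
# Frame geometry operations
# ----------------------------------------------------------------------

def fit_joint_circle(points: np.ndarray, plane_normal: np.ndarray,
                     ) -> tuple[np.ndarray, float]:
    """Least-squares circle through points projected into the sagittal plane.

    The plane passes through the points' centroid with the given unit
    normal.  Returns the circle centre in 3D world coordinates and the
    radius in mm.  Uses the algebraic (Kasa) fit, which is exact for
    noise-free circular data.
    """
    points = np.asarray(points, float)
    n = np.asarray(plane_normal, float)
    n = n / np.linalg.norm(n)
    if len(points) < 3:
        raise DegenerateFitError("need at least 3 points for a circle fit")
    centroid = points.mean(axis=0)
    # in-plane orthonormal basis
    seed = np.array([1.0, 0.0, 0.0])
    if abs(n @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, seed)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    rel = points - centroid
    x = rel @ u
    y = rel @ v
    A = np.column_stack([2 * x, 2 * y, np.ones(len(x))])
    rhs = x ** 2 + y ** 2
    sol, res, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < 3:
        raise DegenerateFitError("projected points are collinear; circle fit degenerate")
    cx, cy, c0 = sol
    r2 = c0 + cx ** 2 + cy ** 2
    if r2 <= 0:
        raise DegenerateFitError("circle fit collapsed to zero radius")
    center = centroid + cx * u + cy * v
    return center, float(np.sqrt(r2))


def compose_spherical(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Rotation matrix from spherical joint angles: flexion ``alpha`` about
    the parent z, abduction ``beta`` about the intermediate axis
    (y_b x z_p direction), internal rotation ``gamma`` about the bone's own
    y-axis.  Intrinsic z-x-y composition."""
    return Rotation.from_euler("ZXY", [alpha, beta, gamma]).as_matrix()


def spherical_angles(bone: BoneFrame, parent: BoneFrame) -> tuple[float, float, float]:
    """Spherical joint angles (alpha, beta, gamma) of ``bone`` relative to
    ``parent``, in radians.

    alpha: signed flexion/extension inside the parent's sagittal plane,
    about the parent z-axis.  beta: signed abduction/adduction, the
    elevation of the bone's y-axis out of that plane.  gamma: residual
    internal rotation about the bone's own y-axis.  The decomposition
    satisfies R_rel = Rz(alpha) Rx(beta) Ry(gamma) in the parent frame.
    """
    R_rel = parent.rotation_matrix.T @ bone.rotation_matrix
    sin_beta = R_rel[2, 1]  # z-component of the bone's y-axis in parent coords
    if abs(sin_beta) > 1.0 - 1e-9:
        raise DegeneratePoseError(
            f"bone y parallel to parent z (beta = {np.sign(sin_beta) * np.pi / 2:+.6f} rad); "
            "flexion/internal rotation are not separable")
    alpha, beta, gamma = Rotation.from_matrix(R_rel).as_euler("ZXY")
    return float(alpha), float(beta), float(gamma)


def flexion_transform(frame_T: RigidTransform, theta: float) -> RigidTransform:
    """Rotation by ``theta`` about the local z-axis of ``frame_T``:
    T Rz(theta) T^-1.  The fixed-point set is exactly the frame's z-axis
    line, so applying it to a child bone flexes the joint."""
    return frame_T @ RigidTransform.rotation_z(theta) @ frame_T.inverse()
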