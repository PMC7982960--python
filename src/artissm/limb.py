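"""The multi-component limb model: surface components + skeleton +
annotations, whole-limb articulation, mirroring, and directory I/O."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .mesh import RigidTransform, TriangleMesh, apply_transform, mirror_mesh, read_mesh, write_mesh
from .schema import LandmarkSchema
from .skeleton import BoneFrame, Skeleton, flexion_transform


@dataclass
class LimbModel:
    """One subject: M component meshes rigidly grouped under the skeleton
    bones, plus optional landmark annotations.

    ``joint_surfaces`` maps a bone id to the vertex set (component label,
    index array) of the articular surface used for joint-circle fitting.
    """

    components: dict[str, TriangleMesh]
    skeleton: Skeleton
    landmarks: LandmarkSchema | None = None
    joint_surfaces: dict[str, tuple[str, np.ndarray]] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        for comp in self.skeleton.component_to_bone:
            if comp not in self.components:
                raise ValueError(f"skeleton maps component {comp!r} that the model lacks")
        self.joint_surfaces = {
            bid: (comp, np.asarray(idx, dtype=np.int64))
            for bid, (comp, idx) in self.joint_surfaces.items()
        }

    @property
    def component_names(self) -> list[str]:
        return list(self.components)

    def vertex_counts(self) -> dict[str, int]:
        return {name: m.n_vertices for name, m in self.components.items()}

    def total_vertices(self) -> int:
        return sum(m.n_vertices for m in self.components.values())

    def copy(self) -> "LimbModel":
        return LimbModel(
            {k: m.copy() for k, m in self.components.items()},
            self.skeleton.copy(),
            self.landmarks,
            {bid: (c, i.copy()) for bid, (c, i) in self.joint_surfaces.items()},
            self.name,
        )

    def transformed(self, t: RigidTransform) -> "LimbModel":
        """Apply one global transform to every component and bone frame."""
        out = self.copy()
        out.components = {k: apply_transform(m, t) for k, m in out.components.items()}
        out.skeleton = Skeleton(
            {bid: b.transformed(t) for bid, b in out.skeleton.bones.items()},
            dict(out.skeleton.component_to_bone),
        )
        return out

    def joint_surface_points(self, bone_id: str) -> np.ndarray:
        comp, idx = self.joint_surfaces[bone_id]
        return self.components[comp].vertices[idx]


def articulate(model: LimbModel, joint_angles: dict[str, float]) -> LimbModel:
    """Flex the limb: rotate each non-root bone about its flexion axis a_b
    (parent z direction through the joint centre c_b) by the given angle.

    ``joint_angles`` maps joint names (MCP, PIP, DIP) to radians.  Every
    component attached to a bone — and everything distal to it — receives
    the same composed rigid transform, so rigid groups stay rigid and
    joint spaces are preserved.
    """
    skel = model.skeleton
    joint_map = skel.joint_to_bone()
    for key in joint_angles:
        if key not in joint_map:
            raise ValueError(f"unknown joint {key!r}; valid joints: {sorted(joint_map)}")
    angles_by_bone = {joint_map[k]: float(v) for k, v in joint_angles.items()}
    for theta in angles_by_bone.values():
        if not np.isfinite(theta):
            raise ValueError("joint angles must be finite")

    # cumulative transform per bone, proximal -> distal, conjugations taken
    # in the *reference* configuration then composed down the chain
    cumulative: dict[str, RigidTransform] = {}
    for bid in skel.topological_order():
        bone = skel.bones[bid]
        if bone.parent_id is None:
            cumulative[bid] = RigidTransform.identity()
            continue
        parent_cum = cumulative[bone.parent_id]
        theta = angles_by_bone.get(bid, 0.0)
        local = flexion_transform(skel.joint_transform(bid), theta)
        cumulative[bid] = parent_cum @ local

    out = model.copy()
    for comp, mesh in out.components.items():
        t = cumulative[skel.component_to_bone[comp]]
        out.components[comp] = apply_transform(mesh, t)
    out.skeleton = Skeleton(
        {bid: b.transformed(cumulative[bid]) for bid, b in skel.bones.items()},
        dict(skel.component_to_bone),
    )
    return out


def mirror_limb(model: LimbModel, plane_normal) -> LimbModel:
    """Mirror a limb through a plane through the origin (e.g. to map right
    limbs onto the left-limb convention).

    Vertices are reflected with face winding reversed (outward orientation
    kept).  Frame x/y axes are reflected and z re-derived as x cross y, which
    restores right-handedness (a raw reflection of all three axes would give
    det = -1) while keeping z perpendicular to the mirrored sagittal plane.
    """
    n = np.asarray(plane_normal, float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-9:
        raise ValueError("plane normal must be a unit vector")

    def refl_v(v):
        return v - 2.0 * (v @ n) * n

    out = model.copy()
    out.components = {k: mirror_mesh(m, n) for k, m in out.components.items()}
    bones = {}
    for bid, b in model.skeleton.bones.items():
        x = refl_v(b.x_axis)
        y = refl_v(b.y_axis)
        z = np.cross(x, y)
        bones[bid] = BoneFrame(bid, x, y, z, refl_v(b.origin), b.parent_id, b.joint_name)
    out.skeleton = Skeleton(bones, dict(model.skeleton.component_to_bone))
    return out


# ----------------------------------------------------------------------
# Directory I/O: one PLY per component + a JSON annotation file
# ----------------------------------------------------------------------

ANNOTATION_FILE = "annotation.json"


def save_limb(model: LimbModel, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    for name, mesh in model.components.items():
        write_mesh(mesh, os.path.join(directory, f"{name}.ply"))
    ann = {
        "name": model.name,
        "components": list(model.components),
        "component_to_bone": dict(model.skeleton.component_to_bone),
        "bones": {
            bid: {
                "x_axis": b.x_axis.tolist(),
                "y_axis": b.y_axis.tolist(),
                "z_axis": b.z_axis.tolist(),
                "origin": b.origin.tolist(),
                "parent": b.parent_id,
                "joint_name": b.joint_name,
            }
            for bid, b in model.skeleton.bones.items()
        },
        "joint_surfaces": {
            bid: {"component": comp, "indices": idx.tolist()}
            for bid, (comp, idx) in model.joint_surfaces.items()
        },
        "landmarks": model.landmarks.to_dict() if model.landmarks else None,
    }
    with open(os.path.join(directory, ANNOTATION_FILE), "w") as fh:
        json.dump(ann, fh, indent=1)


def load_limb(directory: str) -> LimbModel:
    with open(os.path.join(directory, ANNOTATION_FILE)) as fh:
        ann = json.load(fh)
    components = {
        name: read_mesh(os.path.join(directory, f"{name}.ply"), name=name)
        for name in ann["components"]
    }
    bones = {
        bid: BoneFrame(bid, d["x_axis"], d["y_axis"], d["z_axis"], d["origin"],
                       d["parent"], d["joint_name"])
        for bid, d in ann["bones"].items()
    }
    skeleton = Skeleton(bones, ann["component_to_bone"])
    joint_surfaces = {
        bid: (d["component"], np.asarray(d["indices"], dtype=np.int64))
        for bid, d in ann["joint_surfaces"].items()
    }
    landmarks = LandmarkSchema.from_dict(ann["landmarks"]) if ann.get("landmarks") else None
    return LimbModel(components, skeleton, landmarks, joint_surfaces, ann.get("name", ""))
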