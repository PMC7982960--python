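"""Composite shape vectors: geometry + skeleton in one Euclidean vector.

A subject's shape vector concatenates, in a fixed layout,

* the pose/scale-normalized vertex coordinates of all M components
  (3 numbers per vertex),
* per skeleton bone, the logarithmic map of its unit axis direction a_b
  around the population's intrinsic mean mu_b (3 numbers, tangent to S^2),
* per skeleton bone, its joint centre c_b (3 numbers, plain Euclidean —
  centres are points, not directions).

Total length 3F with F = sum_j N_0j + 2 N_b.  The axis directions live on
the unit sphere, so they enter the linear statistics through the tangent
space at their intrinsic means and leave it through the exponential map
(the principal-geodesic treatment); everything else is ordinary PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .limb import LimbModel
from .skeleton import BoneFrame, Skeleton
from .sphere import sphere_exp, sphere_log


class LayoutError(ValueError):
    """Vector length or component sizes disagree with the layout manifest."""


class FrameConstructionError(ValueError):
    """Axis direction nearly parallel to the bone elongation estimate."""


@dataclass
class ShapeVectorLayout:
    """Manifest mapping vector slices to semantics, anchored on a template
    limb (reference topology, skeleton structure, annotations)."""

    template: LimbModel
    component_order: list = field(default_factory=list)
    bone_order: list = field(default_factory=list)
    y_hints: dict = field(default_factory=dict)   # bone -> reference elongation dir

    def __post_init__(self) -> None:
        if not self.component_order:
            self.component_order = list(self.template.components)
        if not self.bone_order:
            self.bone_order = self.template.skeleton.topological_order()
        if not self.y_hints:
            self.y_hints = {bid: self.template.skeleton.bones[bid].y_axis.copy()
                            for bid in self.bone_order}
        self.counts = {c: self.template.components[c].n_vertices
                       for c in self.component_order}

    @property
    def n_bones(self) -> int:
        return len(self.bone_order)

    @property
    def geometry_size(self) -> int:
        return 3 * sum(self.counts.values())

    @property
    def size(self) -> int:
        # 3F with F = sum N_0j + 2 N_b
        return self.geometry_size + 6 * self.n_bones

    def geometry_slice(self, component: str) -> slice:
        start = 0
        for c in self.component_order:
            if c == component:
                return slice(start, start + 3 * self.counts[c])
            start += 3 * self.counts[c]
        raise LayoutError(f"unknown component {component!r}")

    def axis_slice(self, bone: str) -> slice:
        k = self.bone_order.index(bone)
        start = self.geometry_size + 3 * k
        return slice(start, start + 3)

    def center_slice(self, bone: str) -> slice:
        k = self.bone_order.index(bone)
        start = self.geometry_size + 3 * self.n_bones + 3 * k
        return slice(start, start + 3)

    def geometry_block(self, vector: np.ndarray) -> np.ndarray:
        return np.asarray(vector)[..., : self.geometry_size]


def assemble_shape_vector(subject, layout: ShapeVectorLayout,
                          mus: dict[str, np.ndarray]) -> np.ndarray:
    """Flatten a normalized subject (anything with ``components`` and
    ``skeleton``) into a shape vector.  Axis directions a_b (the bone
    frame z-axes) are log-mapped around the intrinsic means ``mus``."""
    parts = []
    for comp in layout.component_order:
        mesh = subject.components[comp]
        if mesh.n_vertices != layout.counts[comp]:
            raise LayoutError(
                f"component {comp!r} has {mesh.n_vertices} vertices, "
                f"layout expects {layout.counts[comp]}")
        parts.append(np.asarray(mesh.vertices, float).ravel())
    skel = subject.skeleton
    axis_parts, center_parts = [], []
    for bid in layout.bone_order:
        b = skel.bones[bid]
        axis_parts.append(sphere_log(b.z_axis / np.linalg.norm(b.z_axis), mus[bid]))
        center_parts.append(np.asarray(b.origin, float))
    return np.concatenate(parts + axis_parts + center_parts)


def disassemble_shape_vector(vector: np.ndarray, layout: ShapeVectorLayout,
                             mus: dict[str, np.ndarray], name: str = "instance",
                             ) -> LimbModel:
    """Inverse of :func:`assemble_shape_vector`: rebuild component meshes
    and a full skeleton.

    Bone frames are reconstructed from the stored (a_b, c_b): z = a_b
    (exp-mapped), y = the component geometry's elongation axis projected
    perpendicular to z (sign fixed by the layout's reference hint),
    x = y cross z.
    """
    vector = np.asarray(vector, float)
    if vector.shape != (layout.size,):
        raise LayoutError(f"vector length {vector.shape} != layout size {layout.size}")
    template = layout.template
    components = {}
    for comp in layout.component_order:
        sl = layout.geometry_slice(comp)
        v = vector[sl].reshape(-1, 3)
        components[comp] = template.components[comp].with_vertices(v)

    skel_t = template.skeleton
    bones = {}
    for bid in layout.bone_order:
        z = sphere_exp(vector[layout.axis_slice(bid)], mus[bid])
        c = vector[layout.center_slice(bid)]
        pts = np.vstack([components[comp].vertices
                         for comp in skel_t.components_of(bid)])
        cov = np.cov((pts - pts.mean(0)).T)
        w, V = np.linalg.eigh(cov)
        y_est = V[:, -1]
        if y_est @ layout.y_hints[bid] < 0:
            y_est = -y_est
        x = np.cross(y_est, z)
        nx = np.linalg.norm(x)
        if nx < 1e-6:
            raise FrameConstructionError(
                f"axis of bone {bid!r} is parallel to its elongation axis")
        x /= nx
        y = np.cross(z, x)
        tb = skel_t.bones[bid]
        bones[bid] = BoneFrame(bid, x, y, z, c, tb.parent_id, tb.joint_name)
    skeleton = Skeleton(bones, dict(skel_t.component_to_bone))
    return LimbModel(components, skeleton, template.landmarks,
                     {b: (c, i.copy()) for b, (c, i) in template.joint_surfaces.items()},
                     name)
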