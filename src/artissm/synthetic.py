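"""Synthetic articulated-limb generator with exact ground truth.

Builds a procedural stand-in for a population of segmented distal-limb
surface models: ten superellipsoid-like components rigidly grouped under
four skeleton bones (metacarpus; P1 + proximal sesamoids; P2; P3 + distal
sesamoid + hoof capsule), with

* articular patches snapped onto analytic cylinders, so joint-circle fits
  have known centres and radii;
* a hoof capsule shell whose dorsal and heel wall lines sit exactly at
  configurable angles to the ground plane, so angle biometrics have known
  values;
* inter-subject shape variation as a small number of orthonormal smooth
  displacement fields (closed-form sinusoids in ambient space, so they can
  be evaluated on any re-sampling of the surface), plus per-subject global
  scale, per-joint flexion, optional abduction remnants and axis-direction
  perturbations, vertex noise, and a random world pose.

Every quantity the downstream pipeline estimates (latent weights, joint
angles, scale, mode subspace, axis directions) is returned as ground truth.
All randomness is driven by the config seed; identical configs give
bit-identical populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .limb import LimbModel, articulate
from .mesh import RigidTransform, TriangleMesh
from .schema import LandmarkSchema
from .skeleton import BoneFrame, Skeleton, flexion_transform


# ----------------------------------------------------------------------
# Parametric primitives
# ----------------------------------------------------------------------

def _ellipsoid(name, center, semi, n_theta, n_phi, asymmetry: float = 1.0):
    """Closed lat-long bone-like blob with poles along y.

    A fixed smooth radial modulation breaks the up/down, dorso-palmar and
    mirror symmetries a plain ellipsoid would have (real bones have
    condyles, ridges and processes; perfectly symmetric primitives would
    make surface registration ill-posed in a way real data is not).  The
    modulation is a closed-form function of the parametric angles, so
    rebuilding at any resolution samples the same continuous surface.

    Returns (mesh, ring) where ring(i, j) gives the vertex index of ring i
    (0 = most distal, n_phi-1 = most proximal) at azimuth j (theta=0 on the
    dorsal +x side).  Index 0 is the bottom (distal) pole, index N-1 the top
    pole.
    """
    center = np.asarray(center, float)
    semi = np.asarray(semi, float)

    def radial_factor(phi, th):
        # dominant single-lobe (1-fold) bulge so no rotation about the bone
        # axis maps the surface near onto itself, plus weaker up/down and
        # 2-fold terms; mimics dorsal ridges / palmar processes
        return 1.0 + asymmetry * (
            0.18 * np.sin(phi) ** 2 * np.cos(th - 0.6)
            + 0.12 * np.sin(phi) * np.cos(phi) * np.sin(th + 0.4)
            + 0.05 * np.sin(phi) ** 2 * np.sin(2 * th + 0.5))

    verts = [center + np.array([0.0, -semi[1], 0.0])]
    for i in range(n_phi):
        phi = np.pi * (i + 1) / (n_phi + 1)
        for j in range(n_theta):
            th = 2 * np.pi * j / n_theta
            f = radial_factor(phi, th)
            verts.append(center + np.array([
                f * semi[0] * np.sin(phi) * np.cos(th),
                -semi[1] * np.cos(phi),
                f * semi[2] * np.sin(phi) * np.sin(th),
            ]))
    verts.append(center + np.array([0.0, semi[1], 0.0]))
    verts = np.asarray(verts)
    top = len(verts) - 1

    def ring(i, j):
        return 1 + i * n_theta + (j % n_theta)

    faces = []
    for j in range(n_theta):  # bottom cap
        faces.append([0, ring(0, j + 1), ring(0, j)])
    for i in range(n_phi - 1):
        for j in range(n_theta):
            a, b = ring(i, j), ring(i, j + 1)
            c, d = ring(i + 1, j), ring(i + 1, j + 1)
            faces.append([a, b, d])
            faces.append([a, d, c])
    for j in range(n_theta):
        faces.append([top, ring(n_phi - 1, j), ring(n_phi - 1, j + 1)])
    mesh = TriangleMesh(verts, np.asarray(faces), name)
    if mesh.signed_volume() < 0:  # ensure outward orientation
        mesh = TriangleMesh(verts, mesh.faces[:, [0, 2, 1]], name)
    return mesh, ring


def _snap_to_cylinder(mesh, idx, center, radius):
    """Project vertices radially (in the x-y plane) onto the cylinder of
    given radius about the z-directed axis through ``center``."""
    c = np.asarray(center, float)
    v = mesh.vertices[idx]
    d = v[:, :2] - c[:2]
    norm = np.linalg.norm(d, axis=1, keepdims=True)
    v[:, :2] = c[:2] + radius * d / norm
    mesh.vertices[idx] = v


def _capsule_shell(name, ground_y, height, dorsal_x, palmar_x, half_width,
                   toe_angle_deg, heel_angle_deg, wall_thickness,
                   n_theta, n_levels):
    """Closed hoof-capsule shell (outer wall, coronet rim, inner wall, sole).

    The dorsal (theta=0) and heel (theta=pi) outer meridians are exact lines
    at the configured angles to the ground plane y = ground_y.
    Returns (mesh, info) with landmark index groups.
    """
    cot_ta = 1.0 / np.tan(np.radians(toe_angle_deg))
    cot_ha = 1.0 / np.tan(np.radians(heel_angle_deg))
    thetas = 2 * np.pi * np.arange(n_theta) / n_theta

    def ring_geom(h, inset):
        dorsal = dorsal_x - h * cot_ta
        palmar = palmar_x + h * cot_ha
        cx = 0.5 * (dorsal + palmar)
        a = 0.5 * (dorsal - palmar) - inset
        b = half_width * (1.0 - 0.25 * h / height) - inset
        x = cx + a * np.cos(thetas)
        # mild medio-lateral asymmetry (vanishes on the dorsal and heel
        # meridians, so the constructed wall angles stay exact); breaks the
        # left-right mirror symmetry a perfect loft would have
        z = b * np.sin(thetas) * (1.0 + 0.10 * np.sin(thetas))
        y = np.full(n_theta, ground_y + h)
        return np.column_stack([x, y, z])

    levels = np.linspace(0.0, height, n_levels + 1)
    verts = []
    outer0 = 0
    for h in levels:
        verts.append(ring_geom(h, 0.0))
    inner0 = (n_levels + 1) * n_theta
    for h in levels[::-1]:  # inner wall runs top -> bottom
        verts.append(ring_geom(h, wall_thickness))
    verts = np.vstack(verts)
    apex_out = len(verts)
    verts = np.vstack([verts, [[0.5 * (dorsal_x + palmar_x), ground_y, 0.0]]])
    apex_in = len(verts)
    verts = np.vstack([verts, [[0.5 * (dorsal_x + palmar_x), ground_y, 0.0]]])
    # inner sole apex slightly above ground to keep the shell non-degenerate
    verts[apex_in, 1] += wall_thickness

    def oring(l, j):
        return outer0 + l * n_theta + (j % n_theta)

    def iring(l, j):  # l = 0 at the coronet (top), n_levels at the sole
        return inner0 + l * n_theta + (j % n_theta)

    faces = []
    for l in range(n_levels):  # outer wall, outward normals
        for j in range(n_theta):
            a, b = oring(l, j), oring(l, j + 1)
            c, d = oring(l + 1, j), oring(l + 1, j + 1)
            faces.append([a, b, d])
            faces.append([a, d, c])
    for j in range(n_theta):  # coronet rim: outer top ring -> inner top ring
        a, b = oring(n_levels, j), oring(n_levels, j + 1)
        c, d = iring(0, j), iring(0, j + 1)
        faces.append([a, b, d])
        faces.append([a, d, c])
    for l in range(n_levels):  # inner wall (normals point into the cavity)
        for j in range(n_theta):
            a, b = iring(l, j), iring(l, j + 1)
            c, d = iring(l + 1, j), iring(l + 1, j + 1)
            faces.append([a, b, d])
            faces.append([a, d, c])
    for j in range(n_theta):  # outer ground cap
        faces.append([apex_out, oring(0, j + 1), oring(0, j)])
    for j in range(n_theta):  # inner sole cap
        faces.append([apex_in, iring(n_levels, j), iring(n_levels, j + 1)])
    mesh = TriangleMesh(verts, np.asarray(faces), name)
    if mesh.signed_volume() < 0:
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, [0, 2, 1]], name)

    j_heel = n_theta // 2  # theta = pi
    # heel buttresses: ground-ring vertices just either side of the heel
    off = max(1, n_theta // 10)
    info = {
        "toe": [oring(0, 0)],
        "coronet_dorsal": [oring(n_levels, 0)],
        "heel_buttress_lateral": [oring(0, j_heel - off)],
        "heel_buttress_medial": [oring(0, j_heel + off)],
        "frog_apex": [apex_out],
        "dorsal_wall_line": [oring(l, 0) for l in range(n_levels + 1)],
        "heel_wall_line": [oring(l, j_heel) for l in range(n_levels + 1)],
        "capsule_wall_lateral": [oring(l, n_theta // 4) for l in range(n_levels + 1)],
        "capsule_wall_medial": [oring(l, 3 * n_theta // 4) for l in range(n_levels + 1)],
        "capsule_band_outer": [oring(n_levels // 2, j) for j in range(n_theta)],
        "capsule_band_inner": [iring(n_levels - n_levels // 2, j) for j in range(n_theta)],
        "ground_contact": [oring(0, j) for j in range(n_theta)] + [apex_out],
    }
    return mesh, info


# ----------------------------------------------------------------------
# Reference limb
# ----------------------------------------------------------------------

#: joint-circle (condyle) radii by articulating bone, mm
_JOINT_RADII = {"P1_group": 12.0, "P2_bone": 10.0, "P3_group": 8.0}
_JOINT_CENTERS = {"P1_group": (0.0, 84.0, 0.0),
                  "P2_bone": (0.0, 40.0, 0.0),
                  "P3_group": (0.0, 14.0, 0.0)}

COMPONENTS = ["MC2", "MC3", "MC4", "PS_med", "PS_lat", "P1", "P2", "P3", "DS", "capsule"]

COMPONENT_TO_BONE = {
    "MC2": "metacarpus", "MC3": "metacarpus", "MC4": "metacarpus",
    "PS_med": "P1_group", "PS_lat": "P1_group", "P1": "P1_group",
    "P2": "P2_bone",
    "P3": "P3_group", "DS": "P3_group", "capsule": "P3_group",
}


def generate_reference_limb(detail: int = 1, toe_angle_deg: float = 50.0,
                            heel_angle_deg: float = 40.0,
                            coffin_angle_deg: float = 50.0,
                            palmar_angle_deg: float = 5.0,
                            ) -> LimbModel:
    """Procedural reference limb (neutral pose, left-limb convention:
    x dorsal, y proximal, z lateral; mm).

    ``detail`` scales mesh resolution.  Wall/aspect angles are exact by
    construction and define the analytic truth for the angle biometrics.
    """
    if detail < 1:
        raise ValueError("detail must be >= 1")
    nt = 12 * detail
    np_big = 9 * detail
    nt_s = 8 * detail
    np_s = 5 * detail

    comps: dict[str, TriangleMesh] = {}
    rings: dict[str, object] = {}

    for name, center, semi, n_t, n_p in [
        ("MC3", (0, 146, 0), (14, 74, 12), nt, np_big),
        ("MC2", (0, 150, -16), (5, 55, 4), nt_s, np_s),
        ("MC4", (0, 150, 16), (5, 55, 4), nt_s, np_s),
        ("P1", (0, 50, 0), (11, 20, 10), nt, np_big),
        ("PS_med", (-12, 68, -7), (4, 6, 3), nt_s, np_s),
        ("PS_lat", (-12, 68, 7), (4, 6, 3), nt_s, np_s),
        ("P2", (0, 17, 0), (10, 11, 9), nt, np_big),
        ("P3", (2, -8, 0), (12, 10, 11), nt, np_big),
        ("DS", (-10, 0, 0), (5, 3.5, 7), nt_s, np_s),
    ]:
        mesh, ring = _ellipsoid(name, center, semi, n_t, n_p)
        comps[name] = mesh
        rings[name] = ring

    capsule, cap_info = _capsule_shell(
        "capsule", ground_y=-22.0, height=22.0, dorsal_x=18.0, palmar_x=-14.0,
        half_width=14.0, toe_angle_deg=toe_angle_deg, heel_angle_deg=heel_angle_deg,
        wall_thickness=3.0, n_theta=16 * detail, n_levels=6 * detail)
    comps["capsule"] = capsule

    schema = LandmarkSchema()
    for lname, idx in cap_info.items():
        schema.add(lname, "capsule", idx)

    # articular patches on the parent bones' distal condyles -> exact cylinders
    joint_surfaces: dict[str, tuple[str, np.ndarray]] = {}
    for bone_id, parent_comp in [("P1_group", "MC3"), ("P2_bone", "P1"), ("P3_group", "P2")]:
        ring = rings[parent_comp]
        idx = np.array([0] + [ring(i, j) for i in range(2 * detail) for j in range(nt)])
        _snap_to_cylinder(comps[parent_comp], idx, _JOINT_CENTERS[bone_id],
                          _JOINT_RADII[bone_id])
        joint_surfaces[bone_id] = (parent_comp, idx)
        schema.add(f"joint_distal_{parent_comp}", parent_comp, idx)

    # MC3 distal joint width / sagittal ridge sets
    patch = joint_surfaces["P1_group"][1]
    schema.add("mc3_distal_joint", "MC3", patch)
    ridge = [i for i in patch if abs(comps["MC3"].vertices[i, 2]) < 3.0 * detail]
    schema.add("sagittal_ridge", "MC3", ridge)

    # proximal articular sets of P1/P2 (top two rings, split medial/lateral)
    for comp in ("P1", "P2"):
        ring = rings[comp]
        top_idx = np.array([ring(i, j) for i in range(np_big - 2 * detail, np_big)
                            for j in range(nt)] + [comps[comp].n_vertices - 1])
        z = comps[comp].vertices[top_idx, 2]
        schema.add(f"{comp.lower()}_prox_medial", comp, top_idx[z <= 0])
        schema.add(f"{comp.lower()}_prox_lateral", comp, top_idx[z >= 0])

    # P3 dorsal (coffin-angle) and solar (palmar-angle) lines, snapped exact
    p3 = comps["P3"]
    ring = rings["P3"]
    dorsal_idx = np.array([ring(i, 0) for i in range(detail, np_big - detail)])
    mid = dorsal_idx[len(dorsal_idx) // 2]
    x_mid, y_mid = p3.vertices[mid, 0], p3.vertices[mid, 1]
    for i in dorsal_idx:
        y = p3.vertices[i, 1]
        p3.vertices[i, 0] = x_mid - (y - y_mid) / np.tan(np.radians(coffin_angle_deg))
        p3.vertices[i, 2] = 0.0
    schema.add("p3_dorsal_line", "P3", dorsal_idx)

    solar_idx = np.array([ring(0, nt // 2), 0, ring(0, 0)])
    y_pole = p3.vertices[0, 1]
    x_pole = p3.vertices[0, 0]
    for i in solar_idx:
        x = p3.vertices[i, 0]
        p3.vertices[i, 1] = y_pole + (x - x_pole) * np.tan(np.radians(palmar_angle_deg))
        p3.vertices[i, 2] = 0.0
    schema.add("p3_palmar_line", "P3", solar_idx)
    schema.add("p3_tip", "P3", [int(ring(0, 0))])

    bones = {
        "metacarpus": BoneFrame("metacarpus", [1, 0, 0], [0, 1, 0], [0, 0, 1],
                                (0.0, 146.0, 0.0), None, None),
        "P1_group": BoneFrame("P1_group", [1, 0, 0], [0, 1, 0], [0, 0, 1],
                              _JOINT_CENTERS["P1_group"], "metacarpus", "MCP"),
        "P2_bone": BoneFrame("P2_bone", [1, 0, 0], [0, 1, 0], [0, 0, 1],
                             _JOINT_CENTERS["P2_bone"], "P1_group", "PIP"),
        "P3_group": BoneFrame("P3_group", [1, 0, 0], [0, 1, 0], [0, 0, 1],
                              _JOINT_CENTERS["P3_group"], "P2_bone", "DIP"),
    }
    skeleton = Skeleton(bones, dict(COMPONENT_TO_BONE))
    comps = {name: comps[name] for name in COMPONENTS}
    model = LimbModel(comps, skeleton, schema, joint_surfaces, name="reference")
    schema.validate(model.components)
    return model


# ----------------------------------------------------------------------
# Population generator
# ----------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic population.

    Mode amplitudes are RMS per-vertex displacements in mm; pose ranges are
    half-widths of uniform flexion offsets per joint in radians; the scale
    range is uniform.  ``remesh`` re-samples every subject surface at a
    different resolution so dense correspondence must be re-established by
    elastic registration.
    """

    n_subjects: int = 20
    n_latent_modes: int = 3
    mode_sds: tuple = (1.0, 0.7, 0.4)
    pose_range: dict = field(default_factory=lambda: {"MCP": 0.35, "PIP": 0.35, "DIP": 0.35})
    scale_range: tuple = (0.9, 1.1)
    noise_sd: float = 0.0
    abduction_sd: float = 0.0
    axis_cone_deg: float = 0.0
    remesh: bool = False
    world_translation: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.mode_sds) < self.n_latent_modes:
            raise ValueError("need one amplitude sd per latent mode")
        if any(s < 0 for s in self.mode_sds) or self.noise_sd < 0:
            raise ValueError("amplitude/noise sds must be non-negative")


@dataclass
class SyntheticGroundTruth:
    """Everything the pipeline is supposed to recover."""

    config: SyntheticConfig
    weights: np.ndarray               # (n_subjects, K) standard-normal latents
    angles: list                      # per subject {joint: radians}
    abductions: list                  # per subject {joint: radians}
    scales: np.ndarray
    world_poses: list                 # per subject RigidTransform
    mode_matrix: np.ndarray           # (3G, K) orthogonal columns (geometry block)
    mode_fields: object               # the ModeBasis (analytic fields), or None
    normalized_subjects: list         # neutral-pose, unit-scale LimbModels
    axes: list                        # per subject {bone: unit flexion-axis direction}


def _smoothed_normals(mesh, radius: float = 12.0) -> np.ndarray:
    """Outward direction field: vertex normals averaged over a fixed
    metric radius (mm).  Smooth in space and consistent between different
    discretizations of the same surface."""
    from scipy.spatial import cKDTree

    n = mesh.vertex_normals()
    tree = cKDTree(mesh.vertices)
    groups = tree.query_ball_point(mesh.vertices, radius)
    out = np.empty_like(n)
    for i, idx in enumerate(groups):
        v = n[idx].mean(axis=0)
        nv = np.linalg.norm(v)
        out[i] = n[i] if nv < 1e-9 else v / nv
    return out


class ModeBasis:
    """Closed-form orthonormal shape-mode displacement fields.

    The raw fields are smooth ambient sinusoids gated per component; they
    vanish on the metacarpal components (the root bone defines the global
    scale/pose datum, so shape variation there would be indistinguishable
    from scale and acquisition pose), and they are projected orthogonal to
    every joint's infinitesimal-rotation field (z_j x (p - c_j) on the
    joint's bone), so shape variation is exactly separable from flexion.
    The final modes are fixed linear combinations of analytic fields,
    hence evaluable on *any* re-sampling of the reference surfaces.
    """

    def __init__(self, reference: LimbModel, k: int, rng: np.random.Generator):
        skel = reference.skeleton
        self.root_components = set(skel.components_of(skel.root_id))
        n_raw = 2 * max(k, 1)
        self.waves = rng.normal(size=(n_raw, 3))
        self.waves /= np.linalg.norm(self.waves, axis=1, keepdims=True)
        self.lams = rng.uniform(60.0, 120.0, size=n_raw)
        self.phases = rng.uniform(0, 2 * np.pi, size=n_raw)
        # allometric weighting: displacement amplitude proportional to the
        # component's size, so a sesamoid varies sub-millimetre while the
        # phalanges vary millimetres (uniform-in-mm fields would deform
        # small bones by a large fraction of their own size)
        sizes = {c: float(np.linalg.norm(m.vertices - m.centroid(), axis=1).mean())
                 for c, m in reference.components.items()}
        ref_size = max(sizes.values())
        self.comp_scale = {c: s / ref_size for c, s in sizes.items()}
        # displacements act along the outward surface normal: a tangential
        # field is a re-parametrization of the same surface, not a shape
        # change, so genuine shape modes are normal fields (and only those
        # are observable from surface geometry).  Normals are averaged over
        # a fixed metric radius so the direction field is smooth and agrees
        # across re-meshings of the same surface.
        # nuisance generators: the full per-bone similarity algebra (3
        # translations, 3 rotations about the bone centroid, 1 scale) for
        # every non-root bone.  Shape modes are constructed orthogonal to
        # all of them, i.e. they live in the Procrustes quotient: any field
        # component resembling a rigid/scale motion of a bone would be
        # indistinguishable from pose or alignment, not shape.  (The joint
        # flexion generators lie inside this span, so pose normalization
        # is exactly unbiased by shape variation.)
        self.nuisances = []  # (frozenset comps, kind, vector, centre)
        eye = np.eye(3)
        for bid in skel.topological_order():
            b = skel.bones[bid]
            if b.parent_id is None:
                continue
            comps = frozenset(skel.components_of(bid))
            centroid = np.vstack([reference.components[c].vertices
                                  for c in comps]).mean(axis=0)
            for ax in range(3):
                self.nuisances.append((comps, "trans", eye[ax], centroid))
            for ax in range(3):
                self.nuisances.append((comps, "rot", eye[ax], centroid))
            self.nuisances.append((comps, "scale", None, centroid))
        self.k = k

        # build the coefficient matrix on the reference discretization
        comps = [(name, m.vertices, _smoothed_normals(m))
                 for name, m in reference.components.items()]
        G = sum(len(v) for _, v, _ in comps)
        A = np.column_stack([
            np.concatenate([self._raw(m, name, v, n).ravel() for name, v, n in comps])
            for m in range(n_raw)])
        R_nuis = np.column_stack([
            np.concatenate([self._nuisance(j, name, v).ravel() for name, v, _ in comps])
            for j in range(len(self.nuisances))])
        # project raw fields orthogonal to the joint-rotation fields
        Qn, _ = np.linalg.qr(R_nuis)
        coeff_n = Qn.T @ A                       # components along nuisances
        A_perp = A - Qn @ coeff_n
        Q, R = np.linalg.qr(A_perp)
        sel = np.abs(np.diag(R)) > 1e-9 * max(np.abs(np.diag(R)).max(), 1.0)
        if sel.sum() < k:
            raise ValueError("could not build enough independent mode fields")
        keep = np.flatnonzero(sel)[:k]
        # modes = A @ C_raw + R_nuis @ C_nuis, orthonormal then scaled to
        # unit RMS per-vertex displacement over the vertices the fields act
        # on (the non-root components), so an amplitude in mm means a local
        # per-vertex displacement of that order
        G_act = sum(len(v) for name, v, _ in comps
                    if name not in self.root_components)
        C = np.linalg.lstsq(A_perp, Q[:, keep], rcond=None)[0]
        self.C_raw = C * np.sqrt(G_act)
        self.C_nuis = -(np.linalg.lstsq(R_nuis, Qn @ (coeff_n @ C), rcond=None)[0]
                        ) * np.sqrt(G_act)
        self.matrix = Q[:, keep] * np.sqrt(G_act)  # (3G, k), columns norm sqrt(G_act)

    def _raw(self, m, component, points, normals):
        if component in self.root_components:
            return np.zeros((len(points), 3))
        points = np.asarray(points, float)
        s = np.sin((points @ self.waves[m])
                   * (2 * np.pi / self.lams[m]) + self.phases[m])
        return self.comp_scale[component] * s[:, None] * np.asarray(normals, float)

    def _nuisance(self, j, component, points):
        comps, kind, vec, c = self.nuisances[j]
        points = np.asarray(points, float)
        if component not in comps:
            return np.zeros((len(points), 3))
        if kind == "trans":
            return np.tile(vec, (len(points), 1))
        if kind == "rot":
            return np.cross(vec, points - c)
        return points - c  # scale

    def displacement(self, component: str, mesh, scaled_weights: np.ndarray,
                     ) -> np.ndarray:
        """Sum_k w_k * mode_k evaluated on a component mesh (any
        discretization of the component surface)."""
        points = mesh.vertices
        normals = _smoothed_normals(mesh)
        out = np.zeros((len(points), 3))
        w_raw = self.C_raw @ scaled_weights
        w_nui = self.C_nuis @ scaled_weights
        for m in range(len(w_raw)):
            if w_raw[m] != 0.0:
                out += w_raw[m] * self._raw(m, component, points, normals)
        for j in range(len(w_nui)):
            if w_nui[j] != 0.0:
                out += w_nui[j] * self._nuisance(j, component, points)
        return out


def _perturbed_frames(skeleton: Skeleton, rng, cone_deg: float) -> Skeleton:
    bones = {}
    for bid, b in skeleton.bones.items():
        if cone_deg > 0:
            angle = np.radians(cone_deg) * rng.uniform(0, 1) ** 0.5
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            R = Rotation.from_rotvec(angle * axis).as_matrix()
        else:
            R = np.eye(3)
        bones[bid] = BoneFrame(bid, R @ b.x_axis, R @ b.y_axis, R @ b.z_axis,
                               b.origin.copy(), b.parent_id, b.joint_name)
    return Skeleton(bones, dict(skeleton.component_to_bone))


def _pose_chain(model: LimbModel, flexions: dict, abductions: dict) -> LimbModel:
    """Articulate with per-joint flexion plus optional abduction remnants."""
    if not abductions or all(abs(v) < 1e-15 for v in abductions.values()):
        return articulate(model, flexions)
    skel = model.skeleton
    joint_map = skel.joint_to_bone()
    cumulative = {}
    from .mesh import apply_transform

    def rot_x(phi):
        c, s = np.cos(phi), np.sin(phi)
        return RigidTransform.from_parts(
            np.array([[1, 0, 0], [0, c, -s], [0, s, c]]), np.zeros(3))

    for bid in skel.topological_order():
        bone = skel.bones[bid]
        if bone.parent_id is None:
            cumulative[bid] = RigidTransform.identity()
            continue
        jname = bone.joint_name
        T = skel.joint_transform(bid)
        theta = float(flexions.get(jname, 0.0))
        phi = float(abductions.get(jname, 0.0))
        local = T @ RigidTransform.rotation_z(theta) @ rot_x(phi) @ T.inverse()
        cumulative[bid] = cumulative[bone.parent_id] @ local
    out = model.copy()
    for comp, mesh in out.components.items():
        out.components[comp] = apply_transform(mesh, cumulative[skel.component_to_bone[comp]])
    out.skeleton = Skeleton(
        {bid: b.transformed(cumulative[bid]) for bid, b in skel.bones.items()},
        dict(skel.component_to_bone))
    return out


def generate_population(reference: LimbModel, config: SyntheticConfig,
                        ) -> tuple[list[LimbModel], SyntheticGroundTruth]:
    """Draw a population of articulated, scaled, posed subjects.

    Subject i is built as ``world_i ( articulate( scale_i * (ref + sum_k
    w_ik sd_k mode_k + noise), theta_i ) )``.  When ``remesh`` is set the
    subject surfaces are re-sampled at a different resolution (the smooth
    deformation fields are closed-form, so the re-sampled surfaces lie on
    the same deformed geometry) and vertex correspondence with the
    reference is destroyed.
    """
    rng = np.random.default_rng(config.seed)
    K = config.n_latent_modes
    basis = ModeBasis(reference, K, rng) if K > 0 else None
    M = basis.matrix if basis else np.zeros((3 * sum(
        m.n_vertices for m in reference.components.values()), 0))
    sds = np.asarray(config.mode_sds[:K], float)

    subjects, truth_norm, angles_all, abd_all, poses, axes_all = [], [], [], [], [], []
    weights = rng.standard_normal((config.n_subjects, K)) if K > 0 else np.zeros((config.n_subjects, 0))
    scales = rng.uniform(config.scale_range[0], config.scale_range[1], config.n_subjects)

    for i in range(config.n_subjects):
        sw = weights[i] * sds if K > 0 else np.zeros(0)

        def displace(comp, mesh):
            if basis is None:
                return np.zeros((mesh.n_vertices, 3))
            return basis.displacement(comp, mesh, sw)

        base = reference.copy()
        for comp, mesh in base.components.items():
            d = displace(comp, mesh)
            if config.noise_sd > 0:
                d = d + rng.normal(0, config.noise_sd, size=mesh.vertices.shape)
            base.components[comp] = mesh.with_vertices(mesh.vertices + d)
        base.skeleton = _perturbed_frames(base.skeleton, rng, config.axis_cone_deg)
        truth_norm.append(base.copy())
        axes_all.append({bid: base.skeleton.bones[base.skeleton.bones[bid].parent_id].z_axis.copy()
                         for bid in base.skeleton.bones if base.skeleton.bones[bid].parent_id})

        flex = {j: rng.uniform(-r, r) for j, r in config.pose_range.items()}
        abd = {j: rng.normal(0, config.abduction_sd) if config.abduction_sd > 0 else 0.0
               for j in config.pose_range}
        angles_all.append(flex)
        abd_all.append(abd)

        subj = base
        if config.remesh:
            subj = _redetail_like(reference)
            for comp, mesh in subj.components.items():
                d = displace(comp, mesh)
                if config.noise_sd > 0:
                    d = d + rng.normal(0, config.noise_sd, size=mesh.vertices.shape)
                subj.components[comp] = mesh.with_vertices(mesh.vertices + d)
            subj.skeleton = base.skeleton.copy()
            subj.landmarks = None
            subj.joint_surfaces = {}

        s = float(scales[i])
        subj = subj.transformed(RigidTransform.from_parts(np.eye(3), np.zeros(3), s))
        subj = _pose_chain(subj, flex, abd)
        Rw = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
        tw = rng.uniform(-config.world_translation, config.world_translation, 3)
        pose = RigidTransform.from_parts(Rw, tw)
        subj = subj.transformed(pose)
        subj.name = f"subject_{i:03d}"
        poses.append(pose)
        subjects.append(subj)

    truth = SyntheticGroundTruth(
        config=config, weights=weights, angles=angles_all, abductions=abd_all,
        scales=scales, world_poses=poses, mode_matrix=M, mode_fields=basis,
        normalized_subjects=truth_norm, axes=axes_all)
    return subjects, truth


def _redetail_like(reference: LimbModel) -> LimbModel:
    """Rebuild the default-parameter reference geometry at a different mesh
    resolution (same continuous surfaces, correspondence destroyed)."""
    return generate_reference_limb(detail=2)
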