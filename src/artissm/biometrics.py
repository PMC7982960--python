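"""Hoof and bone biometrics, their regression against mode weights, and
the linearity (confidence-interval) analysis.

Biometrics are scalar linear or angular measures computed directly on the
3D models.  Because every registered subject and every synthesized
instance shares the reference topology, landmark vertex sets defined once
on the reference transfer automatically, and each biometric becomes a
deterministic function of the geometry: distances between landmark
centroids, angles of best-fit landmark lines against the ground plane,
circle-fit radii of articular patches, extents along bone-frame axes.

The link to the shape model is a per-mode linear regression of the weight
vector on the biometric value, b(k) = alpha + beta k, fitted on simulated
instances; driving the model through b(k) morphs the whole limb
consistently with a prescribed biometric value.  Recomputing the
biometric on the morphed instance and comparing with the requested value
measures how nonlinear the biometric-to-weight relation is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .limb import LimbModel
from .model import ShapeModelResults
from .schema import LandmarkSchema, SchemaError
from .skeleton import fit_joint_circle

#: measurement units per biometric id
UNITS = {
    "FL": "mm", "FW": "mm", "HA": "deg", "HW": "mm", "SL": "mm", "TA": "deg",
    "TL": "mm", "UR": "deg", "WT": "mm", "CA": "deg", "PA": "deg", "CD": "deg",
    "TS": "%", "CR_MC3": "mm", "CR_P1": "mm", "CR_P2": "mm", "AD_P1": "mm",
    "AD_P2": "mm", "AW_P1": "mm", "AW_P2": "mm", "PL_P1": "mm", "PL_P2": "mm",
    "MW": "mm", "RW": "mm", "SA": "deg", "SH": "mm",
}

BIOMETRIC_IDS = tuple(UNITS)


# ----------------------------------------------------------------------
# geometric primitives
# ----------------------------------------------------------------------

def _fit_line_direction(points: np.ndarray) -> np.ndarray:
    c = points.mean(axis=0)
    _, _, Vt = np.linalg.svd(points - c)
    return Vt[0]


def ground_plane(model: LimbModel, schema: LandmarkSchema,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares ground plane (point, unit normal oriented proximally).

    Uses the schema's ``ground_contact`` vertex set when present, else the
    lowest 2% of capsule vertices along the root frame's y-axis.
    """
    up = model.skeleton.bones[model.skeleton.root_id].y_axis
    if "ground_contact" in schema:
        pts = schema.points(model, "ground_contact")
    else:
        verts = model.components["capsule"].vertices
        h = verts @ up
        k = max(4, int(np.ceil(0.02 * len(verts))))
        pts = verts[np.argsort(h)[:k]]
    c = pts.mean(axis=0)
    _, _, Vt = np.linalg.svd(pts - c)
    n = Vt[-1]
    if n @ up < 0:
        n = -n
    return c, n


def _angle_to_plane_deg(direction: np.ndarray, normal: np.ndarray) -> float:
    d = direction / np.linalg.norm(direction)
    return float(np.degrees(np.arcsin(np.clip(abs(d @ normal), 0.0, 1.0))))


def _project_to_plane(p: np.ndarray, origin: np.ndarray, normal: np.ndarray) -> np.ndarray:
    return p - ((p - origin) @ normal) * normal


def _line_angle(model, schema, line_name, bid) -> float:
    o, n = ground_plane(model, schema)
    d = _fit_line_direction(schema.points(model, line_name, bid))
    return _angle_to_plane_deg(d, n)


def _extent(points: np.ndarray, axis: np.ndarray) -> float:
    proj = points @ (axis / np.linalg.norm(axis))
    return float(proj.max() - proj.min())


def _palmar_hoof_line(model, schema, bid):
    """(point, in-plane unit direction) of the line through the heel
    buttresses, projected into the ground plane."""
    o, n = ground_plane(model, schema)
    p1 = _project_to_plane(schema.centroid(model, "heel_buttress_medial", bid), o, n)
    p2 = _project_to_plane(schema.centroid(model, "heel_buttress_lateral", bid), o, n)
    d = p2 - p1
    return p1, d / np.linalg.norm(d), o, n


def _dist_point_to_line(p, line_point, line_dir) -> float:
    rel = p - line_point
    return float(np.linalg.norm(rel - (rel @ line_dir) * line_dir))


# ----------------------------------------------------------------------
# the biometric definitions
# ----------------------------------------------------------------------

def _bm_FL(m, s):
    lp, ld, o, n = _palmar_hoof_line(m, s, "FL")
    apex = _project_to_plane(s.centroid(m, "frog_apex", "FL"), o, n)
    return _dist_point_to_line(apex, lp, ld)


def _bm_FW(m, s):
    return float(np.linalg.norm(s.centroid(m, "heel_buttress_medial", "FW")
                                - s.centroid(m, "heel_buttress_lateral", "FW")))


def _bm_HA(m, s):
    return _line_angle(m, s, "heel_wall_line", "HA")


def _bm_TA(m, s):
    return _line_angle(m, s, "dorsal_wall_line", "TA")


def _bm_HW(m, s):
    lat = s.centroid(m, "capsule_wall_lateral", "HW")
    apex = s.centroid(m, "frog_apex", "HW")
    z = m.skeleton.bones[m.skeleton.component_to_bone["capsule"]].z_axis
    return float(abs((lat - apex) @ z))


def _bm_SL(m, s):
    lp, ld, o, n = _palmar_hoof_line(m, s, "SL")
    toe = _project_to_plane(s.centroid(m, "toe", "SL"), o, n)
    return _dist_point_to_line(toe, lp, ld)


def _bm_TL(m, s):
    return float(np.linalg.norm(s.centroid(m, "toe", "TL")
                                - s.centroid(m, "coronet_dorsal", "TL")))


def _bm_UR(m, s):
    return _bm_HA(m, s) - _bm_TA(m, s)


def _bm_WT(m, s):
    outer = s.points(m, "capsule_band_outer", "WT")
    inner = s.points(m, "capsule_band_inner", "WT")
    d = np.linalg.norm(outer[:, None, :] - inner[None, :, :], axis=2)
    return float(d.min(axis=1).mean())


def _bm_CA(m, s):
    return _line_angle(m, s, "p3_dorsal_line", "CA")


def _bm_PA(m, s):
    return _line_angle(m, s, "p3_palmar_line", "PA")


def _bm_CD(m, s):
    return _bm_CA(m, s) - _bm_TA(m, s)


def _bm_TS(m, s):
    lp, ld, o, n = _palmar_hoof_line(m, s, "TS")
    toe = _project_to_plane(s.centroid(m, "toe", "TS"), o, n)
    sl = _dist_point_to_line(toe, lp, ld)
    # centre of articulation of the distal phalanx = its frame origin
    distal_bone = m.skeleton.component_to_bone["P3"]
    c4 = _project_to_plane(m.skeleton.bones[distal_bone].origin, o, n)
    # dorsal support direction: from the palmar line's foot point to the toe
    foot = lp + ((toe - lp) @ ld) * ld
    d = toe - foot
    d /= np.linalg.norm(d)
    tc = float((toe - c4) @ d)
    return 100.0 * tc / sl


def _joint_radius(m, s, set_name, bone_id):
    pts = s.points(m, set_name, set_name)
    normal = m.skeleton.bones[bone_id].z_axis
    _, r = fit_joint_circle(pts, normal)
    return float(r)


def _bm_CR_MC3(m, s):
    return _joint_radius(m, s, "joint_distal_MC3", m.skeleton.component_to_bone["MC3"])


def _bm_CR_P1(m, s):
    return _joint_radius(m, s, "joint_distal_P1", m.skeleton.component_to_bone["P1"])


def _bm_CR_P2(m, s):
    return _joint_radius(m, s, "joint_distal_P2", m.skeleton.component_to_bone["P2"])


def _articular(m, s, comp, axis_attr):
    bid = m.skeleton.component_to_bone[comp]
    frame = m.skeleton.bones[bid]
    axis = getattr(frame, axis_attr)
    med = _extent(s.points(m, f"{comp.lower()}_prox_medial", comp), axis)
    lat = _extent(s.points(m, f"{comp.lower()}_prox_lateral", comp), axis)
    return 0.5 * (med + lat)


def _bm_AD_P1(m, s):
    return _articular(m, s, "P1", "y_axis")


def _bm_AD_P2(m, s):
    return _articular(m, s, "P2", "y_axis")


def _bm_AW_P1(m, s):
    return _articular(m, s, "P1", "x_axis")


def _bm_AW_P2(m, s):
    return _articular(m, s, "P2", "x_axis")


def _bm_PL(m, s, comp):
    bid = m.skeleton.component_to_bone[comp]
    return _extent(m.components[comp].vertices, m.skeleton.bones[bid].y_axis)


def _bm_MW(m, s):
    bid = m.skeleton.component_to_bone["MC3"]
    return _extent(s.points(m, "mc3_distal_joint", "MW"), m.skeleton.bones[bid].z_axis)


def _bm_RW(m, s):
    bid = m.skeleton.component_to_bone["MC3"]
    return _extent(s.points(m, "sagittal_ridge", "RW"), m.skeleton.bones[bid].z_axis)


def _bm_SA(m, s):
    pa_dir = _fit_line_direction(s.points(m, "p3_palmar_line", "SA"))
    tip = s.centroid(m, "p3_tip", "SA")
    ds_com = m.components["DS"].centroid()
    link = ds_com - tip
    link /= np.linalg.norm(link)
    return float(np.degrees(np.arccos(np.clip(abs(pa_dir @ link), 0.0, 1.0))))


def _bm_SH(m, s):
    bid = m.skeleton.component_to_bone["DS"]
    return _extent(m.components["DS"].vertices, m.skeleton.bones[bid].y_axis)


_DISPATCH = {
    "FL": _bm_FL, "FW": _bm_FW, "HA": _bm_HA, "HW": _bm_HW, "SL": _bm_SL,
    "TA": _bm_TA, "TL": _bm_TL, "UR": _bm_UR, "WT": _bm_WT, "CA": _bm_CA,
    "PA": _bm_PA, "CD": _bm_CD, "TS": _bm_TS, "CR_MC3": _bm_CR_MC3,
    "CR_P1": _bm_CR_P1, "CR_P2": _bm_CR_P2, "AD_P1": _bm_AD_P1,
    "AD_P2": _bm_AD_P2, "AW_P1": _bm_AW_P1, "AW_P2": _bm_AW_P2,
    "PL_P1": lambda m, s: _bm_PL(m, s, "P1"),
    "PL_P2": lambda m, s: _bm_PL(m, s, "P2"),
    "MW": _bm_MW, "RW": _bm_RW, "SA": _bm_SA, "SH": _bm_SH,
}


def compute_biometric(model: LimbModel, schema: LandmarkSchema | None,
                      biometric) -> float:
    """Evaluate one biometric on a limb model in neutral pose.

    ``biometric`` is an id from :data:`BIOMETRIC_IDS` or a callable
    ``f(model) -> float`` (custom measures plug into the regression and CI
    machinery unchanged)."""
    if callable(biometric):
        return float(biometric(model))
    if schema is None:
        schema = model.landmarks
    if schema is None:
        raise SchemaError("model carries no landmark schema")
    try:
        fn = _DISPATCH[biometric]
    except KeyError:
        raise KeyError(f"unknown biometric {biometric!r}; known: {BIOMETRIC_IDS}") from None
    return float(fn(model, schema))


# ----------------------------------------------------------------------
# regression, morphing and the linearity CI
# ----------------------------------------------------------------------

@dataclass
class BiometricRegression:
    """b(k) = alpha + beta k, with the sampled biometric distribution."""

    biometric: str
    alpha: np.ndarray
    beta: np.ndarray
    mean_k: float
    sd_k: float
    n_samples: int

    def weights_for(self, k: float) -> np.ndarray:
        return self.alpha + self.beta * float(k)


def _sampled_biometrics(results: ShapeModelResults, schema, biometrics,
                        n: int, seed: int):
    from .shape_vector import disassemble_shape_vector

    vectors, weights = results.sample(n, seed=seed)
    names = [b if isinstance(b, str) else getattr(b, "__name__", "custom")
             for b in biometrics]
    values = {nm: [] for nm in names}
    for v in vectors:
        limb = disassemble_shape_vector(v, results.layout, results.mus)
        for b, nm in zip(biometrics, names):
            values[nm].append(compute_biometric(limb, schema, b))
    return weights, {nm: np.asarray(vals) for nm, vals in values.items()}, names


def fit_biometric_regression(results: ShapeModelResults, schema,
                             biometric, n: int = 1000, seed: int = 0,
                             ) -> BiometricRegression:
    """Per-mode linear regression of weights on a biometric, fitted on
    ``n`` simulated instances drawn from the model's normal distribution."""
    if n < 10:
        raise ValueError("need n >= 10 simulated instances")
    weights, values, names = _sampled_biometrics(results, schema, [biometric], n, seed)
    k = values[names[0]]
    sd = float(k.std(ddof=1))
    if sd < 1e-12:
        raise ValueError(f"biometric {names[0]!r} has zero variance under sampling")
    A = np.column_stack([np.ones(n), k])
    coef, *_ = np.linalg.lstsq(A, weights, rcond=None)  # (2, n_modes)
    return BiometricRegression(names[0], coef[0], coef[1],
                               float(k.mean()), sd, n)


def instance_from_biometric(reg: BiometricRegression, k: float) -> np.ndarray:
    """Mode weights for a prescribed biometric value (Fig.-5-style morphs
    typically use k = mean +/- 3 sd)."""
    return reg.weights_for(k)


@dataclass
class BiometricCI:
    biometric: str
    grid_k: np.ndarray
    recomputed_k: np.ndarray
    failed: list
    ci_min: float
    ci_max: float


def biometric_ci(results: ShapeModelResults, schema, reg: BiometricRegression,
                 biometric=None, grid: int = 25) -> BiometricCI:
    """Linearity check: for each k on a grid over [mean - 3 sd, mean + 3 sd],
    rebuild the instance from b(k), re-measure the biometric, and report
    the signed range of (k_recomputed - k)."""
    if grid < 3:
        raise ValueError("need a grid of at least 3 values")
    biometric = biometric if biometric is not None else reg.biometric
    ks = np.linspace(reg.mean_k - 3 * reg.sd_k, reg.mean_k + 3 * reg.sd_k, grid)
    recomputed = np.full(len(ks), np.nan)
    failed = []
    for i, k in enumerate(ks):
        try:
            limb = results.instance(reg.weights_for(k))
            recomputed[i] = compute_biometric(limb, schema, biometric)
        except Exception as exc:  # reconstruction failure at extreme k
            failed.append((float(k), repr(exc)))
    diffs = recomputed - ks
    ok = ~np.isnan(diffs)
    return BiometricCI(reg.biometric, ks, recomputed, failed,
                       float(np.nanmin(diffs[ok])), float(np.nanmax(diffs[ok])))


def correlation_table(results: ShapeModelResults, schema, biometrics=None,
                      n: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Pearson correlation matrix of the biometrics under model sampling.

    Constant biometrics get NaN rows/columns (undefined correlation)."""
    if n < 30:
        raise ValueError("need n >= 30 samples for a correlation table")
    biometrics = list(biometrics) if biometrics is not None else list(BIOMETRIC_IDS)
    _, values, names = _sampled_biometrics(results, schema, biometrics, n, seed)
    df = pd.DataFrame(values, columns=names)
    return df.corr()
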