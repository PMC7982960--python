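"""Dense correspondence by elastic registration.

The reference component is rigidly pre-aligned (similarity ICP) and then
elastically deformed onto each subject component with a stiffness-annealed
non-rigid ICP: at each stiffness level the vertex displacement field d
minimizes

    sum_i ||v_i + d_i - p_i||^2  +  lambda * sum_(i,j) in edges ||d_i - d_j||^2

where p_i is the closest point on the target surface.  The quadratic
smoothness term decouples per coordinate, giving three sparse SPD solves
with the graph Laplacian; the stiffness lambda is annealed geometrically
from stiff (near-rigid) to soft (detail-tracking).  The procedure is fully
deterministic (closest-point ties broken by lowest index) and preserves the
reference topology, so the result carries the reference's vertex semantics
onto the subject's geometry.

A second pass re-registers from the vertex-wise mean of the first-pass
results (after pose/scale normalization) to reduce bias toward the chosen
reference subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import identity as sparse_identity
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import factorized

from .distance import SurfaceQuery, signed_geometric_error
from .limb import LimbModel
from .mesh import RigidTransform, TriangleMesh, apply_transform

logger = logging.getLogger(__name__)


@dataclass
class RegistrationParams:
    """Non-rigid ICP controls.

    stiffness_schedule: graph-smoothness weights, annealed high -> low
    (dimensionless; weights the squared displacement difference across each
    mesh edge against squared point-to-surface distance in mm^2).
    iterations_per_level: closest-point updates per stiffness level.
    distance_cap: per-iteration cap on target displacement magnitude (mm);
    guards against far-away wrong matches early in the schedule.
    """

    stiffness_schedule: tuple = (50.0, 20.0, 8.0, 3.0, 1.0, 0.4)
    iterations_per_level: int = 4
    distance_cap: float = 25.0
    icp_iterations: int = 30
    icp_tol: float = 1e-7
    min_target_vertices: int = 100
    normal_shooting: bool = True

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.stiffness_schedule):
            raise ValueError("stiffness values must be positive")


# ----------------------------------------------------------------------
# Rigid/similarity pre-alignment
# ----------------------------------------------------------------------

def _umeyama(src: np.ndarray, dst: np.ndarray, with_scale: bool = True):
    """Least-squares similarity transform src -> dst (Umeyama)."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    A = (dst - mu_d).T @ (src - mu_s) / len(src)
    U, S, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    if with_scale:
        var_s = ((src - mu_s) ** 2).sum() / len(src)
        s = (S @ np.diag([1, 1, d]).diagonal()).sum() / var_s if var_s > 0 else 1.0
    else:
        s = 1.0
    t = mu_d - s * R @ mu_s
    return R, t, float(s)


def _principal_frame(points: np.ndarray):
    c = points.mean(axis=0)
    cov = np.cov((points - c).T)
    w, V = np.linalg.eigh(cov)
    V = V[:, ::-1]  # descending variance
    if np.linalg.det(V) < 0:
        V[:, 2] = -V[:, 2]
    return c, V


@dataclass
class ICPResult:
    transform: RigidTransform
    residual: float
    converged: bool


def rigid_prealign(reference: TriangleMesh, target: TriangleMesh,
                   params: RegistrationParams | None = None,
                   with_scale: bool = True,
                   init: RigidTransform | None = None) -> ICPResult:
    """Similarity transform placing the reference onto the target.

    Without ``init``, the ICP is initialized by aligning centroids and
    principal axes, resolving the principal-axis sign ambiguity by trying
    all four proper-rotation flip hypotheses and keeping the lowest
    residual.  With ``init`` (e.g. a whole-limb alignment when registering
    a single near-symmetric component), the ICP refines from there and no
    flip hypotheses are tried.
    """
    params = params or RegistrationParams()
    if reference.n_vertices == 0 or target.n_vertices == 0:
        raise ValueError("cannot align empty meshes")
    query = SurfaceQuery(target)
    if init is not None:
        s0 = init.scale
        best = (init.rotation, init.translation_vector, s0, np.inf, False)
    else:
        c_r, V_r = _principal_frame(reference.vertices)
        c_t, V_t = _principal_frame(target.vertices)
        flips = [np.diag(f) for f in
                 ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1])]
        best = None
        for F in flips:
            R0 = V_t @ F @ V_r.T
            t0 = c_t - R0 @ c_r
            cand = _run_icp(reference.vertices, query, R0, t0, 1.0,
                            with_scale, n_iter=5, tol=params.icp_tol)
            if best is None or cand[3] < best[3]:
                best = cand
    R, t, s = best[0], best[1], best[2]
    R, t, s, rms, converged = _run_icp(reference.vertices, query, R, t, s,
                                       with_scale, params.icp_iterations, params.icp_tol)
    return ICPResult(RigidTransform.from_parts(R, t, s), rms, converged)


def _run_icp(src, query, R, t, s, with_scale, n_iter, tol):
    """ICP iterations from (R, t, s).  With ``with_scale`` the scale is
    re-estimated each step but clamped near the source/target size ratio
    (free-scale ICP can otherwise collapse the source into a blob lying on
    the target surface); without it the scale stays fixed at the initial
    value."""
    tgt_pts = query.mesh.vertices
    size_ratio = (np.linalg.norm(tgt_pts - tgt_pts.mean(0), axis=1).mean()
                  / np.linalg.norm(src - src.mean(0), axis=1).mean())
    s_lo, s_hi = 0.6 * size_ratio, 1.7 * size_ratio
    s_fixed = s
    prev = np.inf
    rms = np.inf
    converged = False
    for _ in range(n_iter):
        moved = src @ (s * R).T + t
        closest, d, _ = query.closest_points(moved)
        rms = float(np.sqrt((d ** 2).mean()))
        if with_scale:
            R, t, s = _umeyama(src, closest, True)
            if not (s_lo <= s <= s_hi):
                mu_s, mu_d = src.mean(0), closest.mean(0)
                s = float(np.clip(s, s_lo, s_hi))
                t = mu_d - s * R @ mu_s
        else:
            R, t, _ = _umeyama(src * s_fixed, closest, False)
            s = s_fixed
        if abs(prev - rms) < tol:
            converged = True
            break
        prev = rms
    moved = src @ (s * R).T + t
    _, d, _ = query.closest_points(moved)
    return R, t, s, float(np.sqrt((d ** 2).mean())), converged


# ----------------------------------------------------------------------
# Elastic registration
# ----------------------------------------------------------------------

def _laplacian(mesh: TriangleMesh):
    e = mesh.edges()
    n = mesh.n_vertices
    rows = np.concatenate([e[:, 0], e[:, 1], e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0], e[:, 0], e[:, 1]])
    vals = np.concatenate([-np.ones(2 * len(e)), np.ones(2 * len(e))])
    return coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()


def elastic_register(reference: TriangleMesh, target: TriangleMesh,
                     params: RegistrationParams | None = None,
                     force: bool = False, return_trace: bool = False):
    """Deform the (pre-aligned) reference onto the target surface.

    Output keeps the reference vertex count and face list; vertices track
    the target geometry.  Smoothness is annealed over
    ``params.stiffness_schedule``.  With ``return_trace`` also returns the
    mean unsigned point-to-surface distance after each stiffness level.
    """
    params = params or RegistrationParams()
    if target.n_vertices < params.min_target_vertices and not force:
        raise ValueError(
            f"target has {target.n_vertices} < {params.min_target_vertices} vertices; "
            "registration is under-constrained (pass force=True to override)")
    query = SurfaceQuery(target)
    L = _laplacian(reference)
    A_base = (L.T @ L).tocsc()
    eye = sparse_identity(reference.n_vertices, format="csc")
    tri_n = np.cross(target.vertices[target.faces[:, 1]] - target.vertices[target.faces[:, 0]],
                     target.vertices[target.faces[:, 2]] - target.vertices[target.faces[:, 0]])
    tri_n /= np.maximum(np.linalg.norm(tri_n, axis=1, keepdims=True), 1e-30)
    v = reference.vertices.copy()
    trace = []
    for lam in params.stiffness_schedule:
        solve = factorized((eye + lam * A_base).tocsc())
        for _ in range(params.iterations_per_level):
            closest, d, tid = query.closest_points(v)
            delta = closest - v
            if params.normal_shooting:
                # normal shooting (first order): move each vertex along its
                # own normal onto the plane of the closest target facet.
                # Closest-point pulls carry a tangential bias proportional
                # to the target's slope, which makes the correspondence
                # slide across the surface; shooting along the normal
                # removes it.  Fall back to the closest point at grazing
                # incidence or when the shot leaves the facet's vicinity
                # (e.g. across a thin shell).
                n = TriangleMesh(v, reference.faces).vertex_normals()
                m = tri_n[tid]
                ndotm = np.einsum("ij,ij->i", n, m)
                t = np.einsum("ij,ij->i", delta, m) / np.where(
                    np.abs(ndotm) < 1e-12, np.inf, ndotm)
                ok = (np.abs(ndotm) > 0.5) & (np.abs(t) < 1.5 * d + 1.0)
                delta[ok] = t[ok, None] * n[ok]
            dmag = np.linalg.norm(delta, axis=1)
            over = dmag > params.distance_cap
            if over.any():
                delta[over] *= (params.distance_cap / dmag[over])[:, None]
            disp = np.column_stack([solve(delta[:, k]) for k in range(3)])
            v = v + disp
        _, d, _ = query.closest_points(v)
        trace.append(float(d.mean()))
    result = TriangleMesh(v, reference.faces.copy(), reference.name)
    if return_trace:
        return result, trace
    return result


def _ray_surface_offsets(origins: np.ndarray, directions: np.ndarray,
                         target: TriangleMesh, cap: float):
    """Signed offsets t such that origin + t*direction lies on the target
    (Moller-Trumbore over all facets, smallest |t| within the cap wins).
    Returns (t, hit mask)."""
    v0 = target.vertices[target.faces[:, 0]]
    e1 = target.vertices[target.faces[:, 1]] - v0
    e2 = target.vertices[target.faces[:, 2]] - v0
    t_best = np.full(len(origins), np.inf)
    hit = np.zeros(len(origins), dtype=bool)
    chunk = max(1, int(2e6 // max(len(target.faces), 1)))
    for start in range(0, len(origins), chunk):
        o = origins[start:start + chunk][:, None, :]
        d = directions[start:start + chunk][:, None, :]
        p = np.cross(d, e2[None, :, :])
        det = np.einsum("pfi,fi->pf", p, e1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / det
            s = o - v0[None, :, :]
            u = np.einsum("pfi,pfi->pf", s, p) * inv
            q = np.cross(s, e1[None, :, :])
            vv = np.einsum("pfi,pfi->pf", q, np.broadcast_to(d, q.shape)) * inv
            tt = np.einsum("pfi,fi->pf", q, e2) * inv
        eps = 1e-9
        valid = (np.abs(det) > 1e-12) & (u >= -eps) & (vv >= -eps) & (u + vv <= 1 + eps)
        tt = np.where(valid, tt, np.inf)
        tt = np.where(np.abs(tt) <= cap, tt, np.inf)
        k = np.argmin(np.abs(tt), axis=1)
        rows = np.arange(len(k))
        tb = tt[rows, k]
        ok = np.isfinite(tb)
        t_best[start:start + chunk] = np.where(ok, tb, np.inf)
        hit[start:start + chunk] = ok
    return t_best, hit


def normal_shoot_correspondence(placed: TriangleMesh, target: TriangleMesh,
                                cap: float = 15.0) -> tuple[np.ndarray, np.ndarray]:
    """Correspondence by shooting each vertex of the rigidly placed
    reference along its outward direction field onto the target surface.

    Because the offset is a scalar along the direction field, the
    parametrization cannot slide tangentially — which point-to-surface
    registration alone cannot guarantee on smooth, feature-poor regions.
    Returns (new vertex positions, hit mask); misses keep their input
    position and should be resolved by the elastic result.
    """
    from .synthetic import _smoothed_normals

    normals = _smoothed_normals(placed)
    t, hit = _ray_surface_offsets(placed.vertices, normals, target, cap)
    out = placed.vertices.copy()
    out[hit] = placed.vertices[hit] + t[hit, None] * normals[hit]
    return out, hit


# ----------------------------------------------------------------------
# Correspondence building (two-pass) and reporting
# ----------------------------------------------------------------------

@dataclass
class SubjectCorrespondence:
    """Registered meshes (reference topology, subject geometry, subject's
    original world pose) and pre-alignment transforms for one subject."""

    name: str
    meshes: dict[str, TriangleMesh]
    transforms: dict[str, RigidTransform]
    mean_unsigned_error: float = np.nan


@dataclass
class CorrespondenceSet:
    reference: LimbModel
    subjects: list[SubjectCorrespondence]
    skipped: list[str] = field(default_factory=list)

    def check_topology(self) -> None:
        for s in self.subjects:
            for comp, mesh in s.meshes.items():
                ref = self.reference.components[comp]
                assert mesh.n_vertices == ref.n_vertices
                assert np.array_equal(mesh.faces, ref.faces)


def _register_subject(reference: LimbModel, subject: LimbModel,
                      params: RegistrationParams,
                      init_transforms: dict | None = None) -> SubjectCorrespondence:
    """Register every reference component onto one subject.

    Placement is hierarchical: a whole-limb similarity ICP (with flip
    hypotheses — the full limb is asymmetric enough to disambiguate flips
    that individual near-ellipsoidal bones cannot) initializes the root
    bone group; each distal bone group is then rigidly ICP-refined as a
    unit starting from its parent's placement, so only the (bounded)
    per-joint flexion offset remains to be absorbed.  With
    ``init_transforms`` (e.g. the first-pass results during the two-pass
    scheme) all ICP is skipped.
    """
    from .mesh import concatenate_meshes

    skel = reference.skeleton
    bone_T: dict[str, RigidTransform] = {}
    if init_transforms is None:
        # Components arrive labelled (one mesh per anatomical component),
        # so the labelled component centroids are a correspondence-known
        # point set: a similarity Umeyama fit on them gives a global
        # initialization with no flip or azimuth ambiguity (MC2 vs MC4,
        # the sesamoids, DS and the capsule break every near-symmetry of
        # the bone surfaces).  Bone groups with >= 3 non-collinear
        # component centroids get their own centroid fit — those
        # centroids move rigidly with the bone, so the fit already
        # contains the joint flexion; the remaining groups start from
        # their parent's converged placement.  Surface ICP then only
        # refines, it never has to search.
        ref_cent = {c: m.centroid() for c, m in reference.components.items()}
        sub_cent = {c: subject.components[c].centroid() for c in reference.components}
        comps_all = list(reference.components)
        Rg, tg, sg = _umeyama(np.array([ref_cent[c] for c in comps_all]),
                              np.array([sub_cent[c] for c in comps_all]), True)
        global_T = RigidTransform.from_parts(Rg, tg, sg)
        # the subject's scale is global (one factor per limb): estimate it
        # once from all ten centroids and lock it — per-group free-scale
        # ICP is unstable on partially mismatched shapes
        prev = None
        for bid in skel.topological_order():
            comps = skel.components_of(bid)
            init = None
            if len(comps) >= 3:
                rc = np.array([ref_cent[c] for c in comps])
                sc = np.array([sub_cent[c] for c in comps])
                sv = np.linalg.svd(rc - rc.mean(0), compute_uv=False)
                if sv[1] > 0.15 * sv[0]:  # non-collinear triangle
                    R, t, _ = _umeyama(rc * sg, sc, False)
                    init = RigidTransform.from_parts(R, t, sg)
            if init is None:
                init = global_T if prev is None else prev
            group_ref = concatenate_meshes([reference.components[c] for c in comps])
            group_tgt = concatenate_meshes([subject.components[c] for c in comps])
            icp = rigid_prealign(group_ref, group_tgt, params, init=init,
                                 with_scale=False)
            bone_T[bid] = icp.transform
            prev = icp.transform

    # refine each bone group's placement against the *correspondence*
    # rather than the surface: alternate normal-shoot correspondence with
    # a fixed-scale Procrustes re-fit.  A surface-distance ICP optimum is
    # biased by the subject's shape deformation; the Procrustes fit of the
    # shot correspondence is not (shape modes carry no rigid component).
    comp_shot: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if init_transforms is None:
        for bid in skel.topological_order():
            comps = skel.components_of(bid)
            T_b = bone_T[bid]
            s_b = T_b.scale
            for _ in range(4):
                shots, hits, refs = [], [], []
                for c in comps:
                    placed = apply_transform(reference.components[c], T_b)
                    shot, hit = normal_shoot_correspondence(
                        placed, subject.components[c])
                    shots.append(shot)
                    hits.append(hit)
                    refs.append(reference.components[c].vertices)
                all_hit = np.concatenate(hits)
                if all_hit.sum() < 10:
                    break
                src = np.vstack(refs)[all_hit] * s_b
                dst = np.vstack(shots)[all_hit]
                R, t, _ = _umeyama(src, dst, False)
                T_b = RigidTransform.from_parts(R, t, s_b)
            bone_T[bid] = T_b
            for c, shot, hit in zip(comps, shots, hits):
                comp_shot[c] = (shot, hit)

    meshes, transforms, errors = {}, {}, []
    for comp, ref_mesh in reference.components.items():
        target = subject.components[comp]
        if init_transforms is not None:
            placement = init_transforms[comp]
        else:
            placement = bone_T[skel.component_to_bone[comp]]
        placed = apply_transform(ref_mesh, placement)
        registered = elastic_register(placed, target, params, force=True)
        # tangential-gauge repair: keep the elastic position only where the
        # normal shot missed (a scalar offset along the outward direction
        # field cannot slide tangentially; the elastic surface fit can)
        if comp in comp_shot:
            shot, hit = comp_shot[comp]
        else:
            shot, hit = normal_shoot_correspondence(placed, target)
        v = registered.vertices.copy()
        v[hit] = shot[hit]
        registered = TriangleMesh(v, registered.faces, registered.name)
        meshes[comp] = registered
        # T_ij from the dense correspondence itself (more reliable than the
        # surface ICP, which cannot see correspondence)
        R, t, s = _umeyama(ref_mesh.vertices, registered.vertices, with_scale=True)
        transforms[comp] = RigidTransform.from_parts(R, t, s)
        err = signed_geometric_error(registered, target)
        errors.append(err.mean_unsigned)
    return SubjectCorrespondence(subject.name, meshes, transforms,
                                 float(np.mean(errors)))





def build_correspondences(reference: LimbModel, subjects: list[LimbModel],
                          params: RegistrationParams | None = None,
                          two_pass: bool = True) -> CorrespondenceSet:
    """Register the reference onto every subject (per component), then
    optionally repeat from the mean of the normalized first-pass results to
    reduce reference bias.  Outputs stay in each subject's world pose."""
    from .normalization import normalize_subject  # local import: cycle

    params = params or RegistrationParams()
    usable, skipped = [], []
    for s in subjects:
        missing = [c for c in reference.components if c not in s.components]
        if missing:
            logger.warning("skipping subject %s: missing components %s", s.name, missing)
            skipped.append(s.name)
        else:
            usable.append(s)

    pass1 = [_register_subject(reference, s, params) for s in usable]
    cs = CorrespondenceSet(reference, pass1, skipped)
    if not two_pass or len(usable) < 2:
        return cs

    # mean model: average the pose/scale-normalized pass-1 geometries
    normalized = [normalize_subject(sc, reference) for sc in pass1]
    mean_ref = reference.copy()
    for comp in mean_ref.components:
        stack = np.stack([n.components[comp].vertices for n in normalized])
        mean_ref.components[comp] = mean_ref.components[comp].with_vertices(stack.mean(axis=0))
    mean_ref.name = "mean"

    pass2 = [_register_subject(mean_ref, s, params, init_transforms=sc.transforms)
             for s, sc in zip(usable, pass1)]
    return CorrespondenceSet(mean_ref, pass2, skipped)


def correspondence_from_matched(reference: LimbModel, subjects: list[LimbModel],
                                with_scale: bool = True) -> CorrespondenceSet:
    """Correspondence set for subjects that already share the reference
    topology (e.g. synthetic data generated without remeshing): the
    subject meshes are used verbatim and the per-component transforms are
    closed-form similarity fits (no ICP needed)."""
    out = []
    for s in subjects:
        meshes, transforms = {}, {}
        for comp, ref_mesh in reference.components.items():
            tgt = s.components[comp]
            if tgt.n_vertices != ref_mesh.n_vertices:
                raise ValueError(
                    f"component {comp!r} of {s.name!r} does not share the reference "
                    "topology; run build_correspondences instead")
            R, t, sc = _umeyama(ref_mesh.vertices, tgt.vertices, with_scale)
            meshes[comp] = tgt.copy()
            transforms[comp] = RigidTransform.from_parts(R, t, sc)
        out.append(SubjectCorrespondence(s.name, meshes, transforms, 0.0))
    return CorrespondenceSet(reference, out, [])


@dataclass
class RegistrationReport:
    per_vertex_mean: dict[str, np.ndarray]
    per_vertex_sd: dict[str, np.ndarray]
    global_mean_unsigned: float
    global_sd_unsigned: float
    per_subject_mean_unsigned: np.ndarray


def registration_report(cs: CorrespondenceSet, originals: list[LimbModel],
                        ) -> RegistrationReport:
    """Signed-error field statistics across subjects plus the global mean
    unsigned error +/- sd (sd taken across subjects)."""
    by_name = {s.name: s for s in originals}
    signed = {comp: [] for comp in cs.reference.components}
    subj_means = []
    for sc in cs.subjects:
        orig = by_name[sc.name]
        all_abs = []
        for comp, mesh in sc.meshes.items():
            err = signed_geometric_error(mesh, orig.components[comp])
            signed[comp].append(err.distances)
            all_abs.append(np.abs(err.distances))
        subj_means.append(float(np.concatenate(all_abs).mean()))
    per_vertex_mean = {}
    per_vertex_sd = {}
    for comp, stacks in signed.items():
        arr = np.stack(stacks)
        per_vertex_mean[comp] = arr.mean(axis=0)
        per_vertex_sd[comp] = arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros(arr.shape[1])
    subj_means = np.asarray(subj_means)
    return RegistrationReport(
        per_vertex_mean, per_vertex_sd,
        float(subj_means.mean()),
        float(subj_means.std(ddof=1)) if len(subj_means) > 1 else 0.0,
        subj_means)
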