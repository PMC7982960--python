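"""Point-to-surface distances, inside/outside classification and the signed
geometric error used to score registrations.

Sign convention: a query vertex lying *inside* the closed target surface has
a negative distance, one lying outside has a positive distance; points on the
surface get 0 with positive sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import TriangleMesh


def _closest_on_triangles(p: np.ndarray, a, b, c):
    """Closest points on triangles (a, b, c) to points p (all arrays
    broadcastable to (..., 3); vectorized barycentric region clamping,
    Ericson's method)."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("...j,...j->...", ab, ap)
    d2 = np.einsum("...j,...j->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...j,...j->...", ab, bp)
    d4 = np.einsum("...j,...j->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...j,...j->...", ab, cp)
    d6 = np.einsum("...j,...j->...", ac, cp)

    out = np.empty(np.broadcast(a, b, c).shape)
    a, b, c = (np.broadcast_to(x, out.shape) for x in (a, b, c))
    ab = np.broadcast_to(ab, out.shape)
    ac = np.broadcast_to(ac, out.shape)
    done = np.zeros(out.shape[:-1], dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex A
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)  # vertex B
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)  # vertex C
    out[m] = c[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge AB
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d1 / (d1 - d3)
    out[m] = a[m] + t[m, None] * ab[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge AC
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d2 / (d2 - d6)
    out[m] = a[m] + t[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge BC
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    out[m] = b[m] + t[m, None] * (c[m] - b[m])
    done |= m

    m = ~done  # interior
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = vb / denom
        w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


class SurfaceQuery:
    """Reusable nearest-point-on-surface and winding-number queries for one
    target mesh (KD-tree accelerated; exact point--triangle distances)."""

    def __init__(self, mesh: TriangleMesh):
        self.mesh = mesh
        f = mesh.faces
        self._tri = mesh.vertices[f]  # (F, 3, 3)
        centroids = self._tri.mean(axis=1)
        self._centroid_tree = cKDTree(centroids)
        self._vertex_tree = cKDTree(mesh.vertices)
        # circumscribing radius of each triangle around its centroid
        self._tri_radius = np.linalg.norm(self._tri - centroids[:, None, :], axis=2).max(axis=1)
        self._max_radius = float(self._tri_radius.max())

    def closest_points(self, points: np.ndarray, k: int = 24):
        """Return (closest surface points, unsigned distances, triangle ids).

        Candidate triangles are the k centroid-nearest per query point plus
        an exact fallback for points whose candidate distance exceeds the
        provable bound from the nearest-vertex distance.  Ties are broken
        by the lowest triangle index (argmin) for determinism.
        """
        points = np.asarray(points, float)
        n_tri = len(self._tri)
        k = min(k, n_tri)
        _, cand = self._centroid_tree.query(points, k=k)
        cand = np.atleast_2d(cand)
        if cand.shape[0] != len(points):  # k == 1 squeezes
            cand = cand.reshape(len(points), -1)
        tri = self._tri[cand]  # (P, k, 3, 3)
        cp = _closest_on_triangles(points[:, None, :], tri[:, :, 0],
                                   tri[:, :, 1], tri[:, :, 2])
        d2 = np.einsum("pkj,pkj->pk", cp - points[:, None, :], cp - points[:, None, :])
        best = np.argmin(d2, axis=1)
        rows = np.arange(len(points))
        closest = cp[rows, best]
        dists = np.sqrt(d2[rows, best])
        tri_ids = cand[rows, best].astype(np.int64)

        # certified bound: true distance <= nearest-vertex distance; if the
        # candidate answer is worse, re-run those points against all
        # triangles whose centroid could possibly beat it
        ub, _ = self._vertex_tree.query(points)
        bad = np.flatnonzero(dists > ub + 1e-9)
        for i in bad:
            idx = np.asarray(self._centroid_tree.query_ball_point(
                points[i], ub[i] + self._max_radius + 1e-9), dtype=np.int64)
            if idx.size == 0:
                continue
            t = self._tri[idx]
            cpi = _closest_on_triangles(points[i], t[:, 0], t[:, 1], t[:, 2])
            d2i = np.einsum("kj,kj->k", cpi - points[i], cpi - points[i])
            j = int(np.argmin(d2i))
            if d2i[j] < dists[i] ** 2:
                closest[i] = cpi[j]
                dists[i] = np.sqrt(d2i[j])
                tri_ids[i] = idx[j]
        return closest, dists, tri_ids

    def winding_numbers(self, points: np.ndarray, chunk: int = 256) -> np.ndarray:
        """Generalized winding number (solid-angle sum / 4pi); ~1 inside a
        watertight outward-oriented surface, ~0 outside."""
        points = np.asarray(points, float)
        w = np.empty(len(points))
        tri = self._tri
        for start in range(0, len(points), chunk):
            p = points[start:start + chunk]
            a = tri[None, :, 0, :] - p[:, None, :]
            b = tri[None, :, 1, :] - p[:, None, :]
            c = tri[None, :, 2, :] - p[:, None, :]
            la = np.linalg.norm(a, axis=2)
            lb = np.linalg.norm(b, axis=2)
            lc = np.linalg.norm(c, axis=2)
            det = np.einsum("pfi,pfi->pf", a, np.cross(b, c))
            denom = (la * lb * lc
                     + np.einsum("pfi,pfi->pf", a, b) * lc
                     + np.einsum("pfi,pfi->pf", b, c) * la
                     + np.einsum("pfi,pfi->pf", c, a) * lb)
            omega = 2.0 * np.arctan2(det, denom)
            w[start:start + chunk] = omega.sum(axis=1) / (4.0 * np.pi)
        return w

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.winding_numbers(points) > 0.5


@dataclass
class SignedErrorResult:
    """Per-vertex signed distances plus summary statistics (mm)."""

    distances: np.ndarray
    mean: float
    sd: float
    mean_unsigned: float
    unsigned_only: bool = False

    def summary(self) -> dict:
        return {
            "mean_signed_mm": self.mean,
            "sd_signed_mm": self.sd,
            "mean_unsigned_mm": self.mean_unsigned,
            "unsigned_only": self.unsigned_only,
        }


def signed_geometric_error(registered: TriangleMesh, target: TriangleMesh,
                           query: SurfaceQuery | None = None) -> SignedErrorResult:
    """Per-vertex signed distance from ``registered`` vertices to the
    ``target`` surface: negative inside the closed target, positive outside.

    If the target is open (not watertight), the sign cannot be defined and
    unsigned distances are returned with ``unsigned_only=True``.
    """
    if query is None:
        query = SurfaceQuery(target)
    _, d, _ = query.closest_points(registered.vertices)
    unsigned_only = not target.is_watertight()
    if unsigned_only:
        signed = d.copy()
    else:
        # |w| > 1/2 is inside regardless of surface orientation
        inside = np.abs(query.winding_numbers(registered.vertices)) > 0.5
        signed = np.where(inside & (d > 0), -d, d)
    return SignedErrorResult(
        distances=signed,
        mean=float(signed.mean()),
        sd=float(signed.std(ddof=1)) if len(signed) > 1 else 0.0,
        mean_unsigned=float(np.abs(signed).mean()),
        unsigned_only=unsigned_only,
    )
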