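"""Geometry of unit rotation-axis directions on the sphere S^2.

PCA assumes Euclidean data; axis directions live on S^2, so they are mapped
into the tangent plane at their intrinsic (Karcher) mean with the
logarithmic map before statistics, and back with the exponential map after
synthesis (the principal-geodesic-analysis treatment of direction data).
"""

from __future__ import annotations

import numpy as np


class AntipodalError(ValueError):
    """log map is undefined for antipodal pairs."""


def _unit(v: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    v = np.asarray(v, float)
    n = np.linalg.norm(v)
    if abs(n - 1.0) > tol:
        raise ValueError(f"expected a unit vector, |v| = {n:.6g}")
    return v / n


def sphere_log(v, mu) -> np.ndarray:
    """Tangent vector at ``mu`` pointing toward ``v`` with magnitude equal
    to the geodesic angle between them (ambient 3-vector, perpendicular to
    ``mu``)."""
    v = _unit(v)
    mu = _unit(mu)
    c = float(np.clip(v @ mu, -1.0, 1.0))
    if c < -1.0 + 1e-12:
        raise AntipodalError("log map undefined: v is antipodal to mu")
    perp = v - c * mu
    s = np.linalg.norm(perp)
    if s < 1e-15:
        return np.zeros(3)
    return np.arccos(c) * perp / s


def sphere_exp(w, mu) -> np.ndarray:
    """Inverse of :func:`sphere_log`: walk the geodesic from ``mu`` in
    tangent direction ``w`` for arc length |w|."""
    mu = _unit(mu)
    w = np.asarray(w, float)
    w = w - (w @ mu) * mu  # project into the tangent plane for safety
    theta = np.linalg.norm(w)
    if theta < 1e-15:
        return mu.copy()
    return np.cos(theta) * mu + np.sin(theta) * w / theta


def intrinsic_mean(vs, tol: float = 1e-12, max_iter: int = 100):
    """Karcher mean of unit vectors by iterated tangent-space averaging.

    Starts at the normalized Euclidean mean; each step maps all vectors
    into the tangent plane at the current estimate, averages, and walks
    back with the exponential map.  Returns (mean, converged flag); the
    flag is False when the data are not confined to an open hemisphere
    around the iterate (convergence is then not guaranteed).
    """
    vs = np.asarray(vs, float)
    vs = vs / np.linalg.norm(vs, axis=1, keepdims=True)
    mu = vs.mean(axis=0)
    n = np.linalg.norm(mu)
    mu = vs[0].copy() if n < 1e-12 else mu / n
    step_norm = np.inf
    for _ in range(max_iter):
        dots = vs @ mu
        if np.any(dots < -1.0 + 1e-9):
            return mu, False  # some sample (anti)podal to the iterate
        step = np.mean([sphere_log(v, mu) for v in vs], axis=0)
        mu = sphere_exp(step, mu)
        step_norm = float(np.linalg.norm(step))
        if step_norm < tol:
            break
    # the log/exp round trip floors near sqrt(eps) radians for tightly
    # clustered data; treat sub-1e-8 stalls as converged
    converged = step_norm < max(tol, 1e-8)
    hemispherical = bool(np.all(vs @ mu > 0.0))
    return mu, converged and hemispherical
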