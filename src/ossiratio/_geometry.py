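"""Low-level geometry kernels (numba-compiled).

Brute-force ray/triangle and point/triangle queries, adequate for the
mesh sizes this package works at (10^4-10^5 triangles).  Kept free of
any mesh-container dependency: plain float64/int64 arrays in, arrays out.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

__all__ = ["ray_first_hit", "point_mesh_distance"]

_EPS_PARALLEL = 1e-12
# Barycentric slack so rays hitting a shared edge register on both triangles.
_EPS_BARY = 1e-9


@njit(cache=True)
def _ray_triangle(orig, direction, v0, v1, v2):
    """Moller-Trumbore; returns hit distance t or inf (no backface culling)."""
    e1x = v1[0] - v0[0]
    e1y = v1[1] - v0[1]
    e1z = v1[2] - v0[2]
    e2x = v2[0] - v0[0]
    e2y = v2[1] - v0[1]
    e2z = v2[2] - v0[2]
    px = direction[1] * e2z - direction[2] * e2y
    py = direction[2] * e2x - direction[0] * e2z
    pz = direction[0] * e2y - direction[1] * e2x
    det = e1x * px + e1y * py + e1z * pz
    if -_EPS_PARALLEL < det < _EPS_PARALLEL:
        return np.inf
    inv_det = 1.0 / det
    tx = orig[0] - v0[0]
    ty = orig[1] - v0[1]
    tz = orig[2] - v0[2]
    u = (tx * px + ty * py + tz * pz) * inv_det
    if u < -_EPS_BARY or u > 1.0 + _EPS_BARY:
        return np.inf
    qx = ty * e1z - tz * e1y
    qy = tz * e1x - tx * e1z
    qz = tx * e1y - ty * e1x
    v = (direction[0] * qx + direction[1] * qy + direction[2] * qz) * inv_det
    if v < -_EPS_BARY or u + v > 1.0 + _EPS_BARY:
        return np.inf
    t = (e2x * qx + e2y * qy + e2z * qz) * inv_det
    if t <= 0.0:
        return np.inf
    return t


@njit(cache=True, parallel=True)
def ray_first_hit(vertices, faces, origins, directions, exclude, t_min):
    """Distance to the nearest triangle intersection per ray.

    Parameters
    ----------
    vertices : (n, 3) float64
    faces : (m, 3) int64
    origins, directions : (k, 3) float64
        Directions need not be normalized, but distances are in units of
        the direction norm, so callers should pass unit vectors.
    exclude : (k,) int64
        Triangle index to skip for each ray (the ray's source triangle),
        -1 for none.
    t_min : float
        Hits closer than this are discarded as numerical self-hits.

    Returns
    -------
    (k,) float64 distances, inf where the ray misses.
    """
    k = origins.shape[0]
    out = np.empty(k, dtype=np.float64)
    for i in prange(k):
        best = np.inf
        for j in range(faces.shape[0]):
            if j == exclude[i]:
                continue
            t = _ray_triangle(
                origins[i],
                directions[i],
                vertices[faces[j, 0]],
                vertices[faces[j, 1]],
                vertices[faces[j, 2]],
            )
            if t_min < t < best:
                best = t
        out[i] = best
    return out


@njit(cache=True)
def _point_triangle_sq(p, a, b, c):
    """Squared distance point-triangle (Ericson, Real-Time Collision Detection)."""
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    acx, acy, acz = c[0] - a[0], c[1] - a[1], c[2] - a[2]
    apx, apy, apz = p[0] - a[0], p[1] - a[1], p[2] - a[2]
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        return apx * apx + apy * apy + apz * apz
    bpx, bpy, bpz = p[0] - b[0], p[1] - b[1], p[2] - b[2]
    d3 = abx * bpx + aby * bpy + abz * bpz
    d4 = acx * bpx + acy * bpy + acz * bpz
    if d3 >= 0.0 and d4 <= d3:
        return bpx * bpx + bpy * bpy + bpz * bpz
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        t = d1 / (d1 - d3)
        qx = apx - t * abx
        qy = apy - t * aby
        qz = apz - t * abz
        return qx * qx + qy * qy + qz * qz
    cpx, cpy, cpz = p[0] - c[0], p[1] - c[1], p[2] - c[2]
    d5 = abx * cpx + aby * cpy + abz * cpz
    d6 = acx * cpx + acy * cpy + acz * cpz
    if d6 >= 0.0 and d5 <= d6:
        return cpx * cpx + cpy * cpy + cpz * cpz
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        t = d2 / (d2 - d6)
        qx = apx - t * acx
        qy = apy - t * acy
        qz = apz - t * acz
        return qx * qx + qy * qy + qz * qz
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        dx = p[0] - (b[0] + t * (c[0] - b[0]))
        dy = p[1] - (b[1] + t * (c[1] - b[1]))
        dz = p[2] - (b[2] + t * (c[2] - b[2]))
        return dx * dx + dy * dy + dz * dz
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    dx = p[0] - (a[0] + abx * v + acx * w)
    dy = p[1] - (a[1] + aby * v + acy * w)
    dz = p[2] - (a[2] + abz * v + acz * w)
    return dx * dx + dy * dy + dz * dz


@njit(cache=True, parallel=True)
def point_mesh_distance(points, vertices, faces):
    """Unsigned distance from each point to the nearest mesh triangle."""
    n = points.shape[0]
    out = np.empty(n, dtype=np.float64)
    for i in prange(n):
        best = np.inf
        for j in range(faces.shape[0]):
            d = _point_triangle_sq(
                points[i],
                vertices[faces[j, 0]],
                vertices[faces[j, 1]],
                vertices[faces[j, 2]],
            )
            if d < best:
                best = d
        out[i] = np.sqrt(best)
    return out
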