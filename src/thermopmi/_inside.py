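"""Point-in-mesh testing for cubic-grid voxelization.

The primary test is scanline ray-parity casting: for every grid column
(fixed y, z) the +x line is intersected with all triangles once and the
parity of crossings below each cube centre decides inside/outside.
Columns whose ray passes too close to a triangle edge or vertex are
recast with a tiny jittered origin; if the parity is still ambiguous the
generalized winding number (solid-angle sum) decides per cube centre.
"""
from __future__ import annotations

import numpy as np

# Jitter offsets (fractions of dx) tried when a column ray grazes an edge.
_JITTERS = ((1.1e-6, 1.7e-6), (-2.3e-6, 1.3e-6), (1.9e-6, -2.9e-6))
_EDGE_EPS = 1e-9


def winding_number_inside(points: np.ndarray, vertices: np.ndarray,
                          faces: np.ndarray) -> np.ndarray:
    """Generalized winding number test (Van Oosterom & Strackee solid angles).

    Returns a boolean array: True where the summed solid angle exceeds 2*pi,
    i.e. the point is enclosed by the (oriented, closed) surface.
    """
    points = np.atleast_2d(points)
    tri = vertices[faces]  # (m, 3, 3)
    out = np.empty(len(points), dtype=bool)
    for idx, p in enumerate(points):
        a = tri[:, 0] - p
        b = tri[:, 1] - p
        c = tri[:, 2] - p
        la = np.linalg.norm(a, axis=1)
        lb = np.linalg.norm(b, axis=1)
        lc = np.linalg.norm(c, axis=1)
        det = np.einsum("ij,ij->i", a, np.cross(b, c))
        denom = (la * lb * lc + np.einsum("ij,ij->i", a, b) * lc
                 + np.einsum("ij,ij->i", b, c) * la
                 + np.einsum("ij,ij->i", c, a) * lb)
        omega = 2.0 * np.arctan2(det, denom)
        out[idx] = abs(omega.sum()) > 2.0 * np.pi
    return out


def _column_crossings(tri: np.ndarray, yc: float, zc: float):
    """Intersect the line {y=yc, z=zc} with all triangles.

    Returns (crossing_x_values, ambiguous) where ambiguous flags a ray that
    grazes a triangle edge/vertex or lies in a triangle's plane.
    """
    y0, y1, y2 = tri[:, 0, 1], tri[:, 1, 1], tri[:, 2, 1]
    z0, z1, z2 = tri[:, 0, 2], tri[:, 1, 2], tri[:, 2, 2]
    d = (y1 - y0) * (z2 - z0) - (z1 - z0) * (y2 - y0)
    scale = np.maximum(np.abs(d).max(), 1e-30)
    degenerate = np.abs(d) < 1e-12 * scale
    d_safe = np.where(degenerate, 1.0, d)
    # Barycentric coordinates of (yc, zc) in the projected triangle.
    u = ((y1 - yc) * (z2 - zc) - (z1 - zc) * (y2 - yc)) / d_safe
    v = ((y2 - yc) * (z0 - zc) - (z2 - zc) * (y0 - yc)) / d_safe
    w = 1.0 - u - v
    near = ((u > -_EDGE_EPS) & (v > -_EDGE_EPS) & (w > -_EDGE_EPS)
            & (np.minimum(np.minimum(u, v), w) < _EDGE_EPS))
    if np.any(near & ~degenerate):
        return None, True
    # A degenerate (edge-on) triangle only matters if the ray could graze it.
    if np.any(degenerate):
        dg = tri[degenerate]
        in_box = ((dg[:, :, 1].min(axis=1) - 1e-9 <= yc)
                  & (yc <= dg[:, :, 1].max(axis=1) + 1e-9)
                  & (dg[:, :, 2].min(axis=1) - 1e-9 <= zc)
                  & (zc <= dg[:, :, 2].max(axis=1) + 1e-9))
        if np.any(in_box):
            return None, True
    hit = (u > 0.0) & (v > 0.0) & (w > 0.0) & ~degenerate
    if not np.any(hit):
        return np.empty(0), False
    xs = (u[hit] * tri[hit, 0, 0] + v[hit] * tri[hit, 1, 0]
          + w[hit] * tri[hit, 2, 0])
    if len(xs) % 2 != 0:
        return None, True
    return np.sort(xs), False


def component_occupancy(vertices: np.ndarray, faces: np.ndarray,
                        origin: np.ndarray, dx: float,
                        dims: tuple[int, int, int]) -> np.ndarray:
    """Occupancy (cube centre strictly inside the closed surface) per cube."""
    occ = np.zeros(dims, dtype=bool)
    tri = vertices[faces]
    lo = vertices.min(axis=0)
    hi = vertices.max(axis=0)
    xs = origin[0] + (np.arange(dims[0]) + 0.5) * dx
    ys = origin[1] + (np.arange(dims[1]) + 0.5) * dx
    zs = origin[2] + (np.arange(dims[2]) + 0.5) * dx
    ix = np.where((xs > lo[0]) & (xs < hi[0]))[0]
    jy = np.where((ys > lo[1]) & (ys < hi[1]))[0]
    kz = np.where((zs > lo[2]) & (zs < hi[2]))[0]
    if ix.size == 0 or jy.size == 0 or kz.size == 0:
        return occ
    x_centres = xs[ix]
    ymin = tri[:, :, 1].min(axis=1)
    ymax = tri[:, :, 1].max(axis=1)
    for j in jy:
        # Prefilter triangles by their y-extent once per scan plane.
        sel = (ymin <= ys[j] + dx) & (ymax >= ys[j] - dx)
        tri_j = tri[sel]
        if len(tri_j) == 0:
            continue
        for k in kz:
            yc, zc = ys[j], zs[k]
            crossings, ambiguous = _column_crossings(tri_j, yc, zc)
            if ambiguous:
                for dj, dk in _JITTERS:
                    crossings, ambiguous = _column_crossings(
                        tri_j, yc + dj * dx, zc + dk * dx)
                    if not ambiguous:
                        break
            if ambiguous:
                pts = np.column_stack([
                    x_centres,
                    np.full(len(x_centres), yc),
                    np.full(len(x_centres), zc),
                ])
                occ[ix, j, k] = winding_number_inside(pts, vertices, faces)
                continue
            if crossings.size == 0:
                continue
            parity = np.searchsorted(crossings, x_centres) % 2 == 1
            occ[ix, j, k] = parity
    return occ
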