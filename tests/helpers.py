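"""Independent oracles and generators shared across the test modules.

Everything here is deliberately implemented without touching the package's
own geometry code paths, so it can serve as a cross-check.
"""

from __future__ import annotations

import numpy as np


def point_on_segment(p, a, b, tol=1e-9) -> bool:
    p, a, b = (np.asarray(x, dtype=float) for x in (p, a, b))
    ab = b - a
    ap = p - a
    cross = ab[0] * ap[1] - ab[1] * ap[0]
    if abs(cross) > tol * max(1.0, np.linalg.norm(ab)):
        return False
    dot = ap @ ab
    return -tol <= dot <= ab @ ab + tol


def point_in_polygon(p, verts, tol=1e-9) -> bool:
    """Ray-casting point-in-polygon, inclusive of the boundary."""
    p = np.asarray(p, dtype=float)
    verts = np.asarray(verts, dtype=float)
    n = len(verts)
    for i in range(n):
        if point_on_segment(p, verts[i], verts[(i + 1) % n]):
            return True
    inside = False
    x, y = p
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


def random_convex_polygon(rng: np.random.Generator, n_max: int = 10, scale: float = 50.0):
    """Convex polygon built by angle-sorting random points about their mean."""
    n = rng.integers(4, n_max + 1)
    pts = rng.uniform(0, scale, size=(n, 2))
    center = pts.mean(axis=0)
    order = np.argsort(np.arctan2(*(pts - center).T[::-1]))
    ring = pts[order]
    # angle-sorting gives a star polygon; take only points on the convex
    # boundary by repeatedly removing reflex vertices
    changed = True
    while changed and len(ring) > 3:
        changed = False
        keep = []
        m = len(ring)
        for i in range(m):
            a, b, c = ring[(i - 1) % m], ring[i], ring[(i + 1) % m]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross <= 1e-9:
                changed = True
            else:
                keep.append(b)
        if changed and len(keep) >= 3:
            ring = np.asarray(keep)
    return np.asarray(ring)


def brute_force_hull_vertices(points: np.ndarray) -> set:
    """O(n^4) hull: keep points not strictly inside any triangle of others."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    keep = set()
    for i in range(n):
        p = pts[i]
        interior = False
        for a in range(n):
            if interior:
                break
            for b in range(a + 1, n):
                if interior:
                    break
                for c in range(b + 1, n):
                    if i in (a, b, c):
                        continue
                    if _strictly_inside_triangle(p, pts[a], pts[b], pts[c]):
                        interior = True
                        break
        if not interior:
            keep.add((float(p[0]), float(p[1])))
    return keep


def _strictly_inside_triangle(p, a, b, c, tol=1e-12) -> bool:
    def cross(o, u, v):
        return (u[0] - o[0]) * (v[1] - o[1]) - (u[1] - o[1]) * (v[0] - o[0])

    d1, d2, d3 = cross(a, b, p), cross(b, c, p), cross(c, a, p)
    return (d1 > tol and d2 > tol and d3 > tol) or (d1 < -tol and d2 < -tol and d3 < -tol)


def sampled_line_length(point, direction, verts, step: float = 0.01, reach: float = 300.0) -> float:
    """Dense-sampling estimate of the length of a line inside a polygon.

    Walks the line in ``step``-sized increments over [-reach, reach] and
    counts sample points inside the polygon (boundary-inclusive).
    """
    p0 = np.asarray(point, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    ts = np.arange(-reach, reach, step)
    samples = p0[None, :] + ts[:, None] * d[None, :]
    import shapely
    from shapely.geometry import Polygon

    poly = Polygon([tuple(v) for v in verts])
    pts = shapely.points(samples[:, 0], samples[:, 1])
    return float(shapely.covers(poly, pts).sum() * step)


def ellipse_mask(shape, center, semi_major, semi_minor, theta) -> np.ndarray:
    """Analytically rasterized filled ellipse (independent of the package).

    ``theta`` is the major-axis angle measured from the column axis toward
    the row axis, i.e. atan2(d_row, d_col) of the major-axis direction.
    """
    h, w = shape
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dr = rows - center[0]
    dc = cols - center[1]
    u = dr * np.sin(theta) + dc * np.cos(theta)
    v = dr * np.cos(theta) - dc * np.sin(theta)
    return (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0
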