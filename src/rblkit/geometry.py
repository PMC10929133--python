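"""Shape-orientation and hull geometry underlying the bone-loss measurement.

The tooth's long axis is estimated as the principal eigenvector of the
covariance matrix of its set-pixel coordinates (PCA on the mask treated as a
scatter plot).  Root-region extents along that axis are obtained by clipping
the infinite axis line against the convex hull of each region, which bridges
the gap between the roots of multi-rooted teeth so the measured length spans
the whole root region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

_EIG_EPS = 1e-12
#: relative eigenvalue-gap threshold below which the axis direction is
#: considered ill-determined (near-isotropic shape)
DEGENERACY_TOL = 1e-6


class GeometryError(ValueError):
    """Raised for masks or polygons on which an operation is undefined."""


@dataclass(frozen=True)
class PrincipalAxis:
    """Centroid, principal direction and eigenvalues of a pixel scatter.

    ``direction`` is the unit eigenvector of the larger eigenvalue,
    sign-canonicalized to a non-negative row component (ties broken toward a
    non-negative col component).  ``degenerate_flag`` marks near-isotropic
    shapes whose axis direction is numerically meaningless.
    """

    centroid: Tuple[float, float]
    direction: Tuple[float, float]
    minor_direction: Tuple[float, float]
    eigenvalues: Tuple[float, float]  # (lambda_max, lambda_min), pixel^2
    degenerate_flag: bool

    def __post_init__(self) -> None:
        d = np.asarray(self.direction)
        m = np.asarray(self.minor_direction)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9 or abs(np.linalg.norm(m) - 1.0) > 1e-9:
            raise GeometryError("axis directions must be unit vectors")
        if abs(float(d @ m)) > 1e-9:
            raise GeometryError("principal and minor directions must be orthogonal")
        lmax, lmin = self.eigenvalues
        if not (lmax >= lmin >= -1e-9):
            raise GeometryError("eigenvalues must satisfy lambda_max >= lambda_min >= 0")


@dataclass(frozen=True)
class HullPolygon:
    """Convex polygon as an ordered (counter-clockwise) vertex list.

    Degenerate hulls of one point (single vertex) or collinear points (two
    vertices) are representable; convexity is validated for >= 3 vertices.
    """

    vertices: np.ndarray  # (M, 2) float, (row, col)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 1:
            raise GeometryError("hull needs an (M, 2) vertex array with M >= 1")
        if v.shape[0] >= 3:
            crosses = []
            m = v.shape[0]
            for i in range(m):
                a, b, c = v[i], v[(i + 1) % m], v[(i + 2) % m]
                crosses.append(_cross(b - a, c - b))
            crosses = np.asarray(crosses)
            if not ((crosses > 1e-9).all() or (crosses < -1e-9).all()):
                raise GeometryError("vertex list is not strictly convex")
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return self.vertices.shape[0]


@dataclass(frozen=True)
class Ellipse:
    """PCA-aligned circumscribing ellipse of a mask (for display parity)."""

    center: Tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation: float  # radians of the major axis in [0, pi)

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor >= 0):
            raise GeometryError("semi_major >= semi_minor >= 0 required")


def _cross(u: np.ndarray, v: np.ndarray) -> float:
    return float(u[0] * v[1] - u[1] * v[0])


def _canonical_sign(vec: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    if vec[0] < -tol or (abs(vec[0]) <= tol and vec[1] < 0):
        return -vec
    return vec


def mask_coordinates(mask: np.ndarray) -> np.ndarray:
    """Set-pixel center coordinates of a binary mask as an (N, 2) float array."""
    coords = np.argwhere(np.asarray(mask, dtype=bool))
    return coords.astype(float)


def principal_axis(mask: np.ndarray) -> PrincipalAxis:
    """PCA principal axis of a binary mask's set-pixel scatter.

    Covariance uses population (1/N) normalization for determinism across
    platforms; requires at least two set pixels.
    """
    coords = mask_coordinates(mask)
    n = coords.shape[0]
    if n < 2:
        raise GeometryError(f"principal axis needs >= 2 set pixels, got {n}")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / n
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    lmin, lmax = float(max(eigvals[0], 0.0)), float(max(eigvals[1], 0.0))
    major = _canonical_sign(eigvecs[:, 1].copy())
    minor = _canonical_sign(eigvecs[:, 0].copy())
    degenerate = (lmax - lmin) / max(lmax, _EIG_EPS) < DEGENERACY_TOL
    return PrincipalAxis(
        centroid=(float(centroid[0]), float(centroid[1])),
        direction=(float(major[0]), float(major[1])),
        minor_direction=(float(minor[0]), float(minor[1])),
        eigenvalues=(lmax, lmin),
        degenerate_flag=bool(degenerate),
    )


def circumscribing_ellipse(mask: np.ndarray) -> Ellipse:
    """PCA-aligned ellipse scaled to enclose every set pixel center.

    The ellipse is centered at the PCA centroid, oriented along the principal
    axis, with semi-axes proportional to the eigenvalue square roots and
    scaled by the maximum Mahalanobis radius over set pixels.
    """
    axis = principal_axis(mask)
    lmax, lmin = axis.eigenvalues
    if lmin / max(lmax, _EIG_EPS) < 1e-9:
        raise GeometryError(
            "mask pixels are (near-)collinear; circumscribing ellipse undefined "
            "(need >= 3 non-collinear set pixels)"
        )
    coords = mask_coordinates(mask)
    centered = coords - np.asarray(axis.centroid)
    u = np.asarray(axis.direction)
    v = np.asarray(axis.minor_direction)
    d2 = (centered @ u) ** 2 / lmax + (centered @ v) ** 2 / lmin
    r = float(np.sqrt(d2.max()))
    orientation = float(np.arctan2(u[0], u[1]) % np.pi)
    return Ellipse(
        center=axis.centroid,
        semi_major=r * float(np.sqrt(lmax)),
        semi_minor=r * float(np.sqrt(lmin)),
        orientation=orientation,
    )


def convex_hull_points(points: np.ndarray) -> HullPolygon:
    """Monotone-chain convex hull of an (N, 2) point array.

    Collinear boundary points are dropped, so every retained vertex is a
    strict corner.  One unique point yields a single-vertex hull; collinear
    point sets yield the two extreme points.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if pts.shape[0] == 0:
        raise GeometryError("convex hull of an empty point set")
    if pts.shape[0] == 1:
        return HullPolygon(vertices=pts)
    # lexicographic sort (np.unique already sorts rows lexicographically)
    def half(points_iter):
        chain: list = []
        for p in points_iter:
            while len(chain) >= 2 and _cross(chain[-1] - chain[-2], p - chain[-2]) <= 1e-12:
                chain.pop()
            chain.append(p)
        return chain

    lower = half(pts)
    upper = half(pts[::-1])
    verts = np.asarray(lower[:-1] + upper[:-1])
    if verts.shape[0] < 2:  # all collinear -> keep the two extremes
        verts = np.asarray([pts[0], pts[-1]])
    return HullPolygon(vertices=verts)


def convex_hull(mask: np.ndarray) -> HullPolygon:
    """Convex hull of a binary mask's set-pixel centers."""
    coords = mask_coordinates(mask)
    if coords.shape[0] == 0:
        raise GeometryError("convex hull of an empty mask")
    return convex_hull_points(coords)


def line_length_in_hull(
    point: np.ndarray, direction: np.ndarray, hull: HullPolygon
) -> float:
    """Length of the intersection of an infinite line with a convex polygon.

    The line passes through ``point`` along unit ``direction``; the polygon's
    half-planes clip it to (by convexity) a single segment.  Returns 0 when
    the line misses the hull.  Degenerate hulls are handled: a point hull
    contributes length 0; a segment hull contributes its own length when the
    line contains it, else 0.
    """
    p0 = np.asarray(point, dtype=float)
    d = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(d)
    if nrm < 1e-12:
        raise GeometryError("line direction must be non-zero")
    d = d / nrm
    verts = hull.vertices
    m = verts.shape[0]
    if m == 1:
        return 0.0
    if m == 2:
        a, b = verts
        seg = b - a
        if abs(_cross(d, seg)) < 1e-9 and abs(_cross(d, a - p0)) < 1e-9:
            return float(np.linalg.norm(seg))
        return 0.0
    # orientation sign from the shoelace sum
    area2 = sum(_cross(verts[i], verts[(i + 1) % m]) for i in range(m))
    s = 1.0 if area2 > 0 else -1.0
    tmin, tmax = -np.inf, np.inf
    for i in range(m):
        a, b = verts[i], verts[(i + 1) % m]
        e = b - a
        den = s * _cross(e, d)
        num = s * _cross(e, p0 - a)
        if abs(den) < 1e-12:
            if num < -1e-9:
                return 0.0
            continue
        t = -num / den
        if den > 0:
            tmin = max(tmin, t)
        else:
            tmax = min(tmax, t)
    return float(max(0.0, tmax - tmin))


def axis_length_in_hull(axis: PrincipalAxis, hull: HullPolygon) -> float:
    """Length of the principal-axis line inside a convex hull (pixels)."""
    return line_length_in_hull(
        np.asarray(axis.centroid), np.asarray(axis.direction), hull
    )
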