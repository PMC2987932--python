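"""3D analytic-geometry primitives: lines, planes, intersections, closest points.

All lengths are in centimetres and, with a unit time step, displacements are
numerically equal to velocities. Classification tolerances are scale-free:
the skewness test normalises the triple product of the two line directions and
the inter-anchor offset by the product of their magnitudes, so a configuration
classifies the same way after uniform rescaling or a rigid motion.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default scale-free classification tolerance.
DEFAULT_TOL = 1e-9


class GeometryError(ValueError):
    """Invalid or degenerate geometric input."""


class DegenerateLineError(GeometryError):
    """A line was specified by two coincident points."""


class DegeneratePlaneError(GeometryError):
    """A plane was specified by collinear points."""


def as_vec3(v, name: str = "vector") -> np.ndarray:
    """Coerce ``v`` to a finite float vector of shape (3,).

    The floating dtype is preserved: extended-precision (``np.longdouble``)
    input stays extended-precision, so ill-conditioned constructions can be
    carried out with a wider mantissa; everything else becomes float64.
    """
    arr = np.asarray(v)
    if arr.dtype != np.longdouble:
        arr = arr.astype(float)
    if arr.shape != (3,):
        raise GeometryError(f"{name} must have shape (3,), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise GeometryError(f"{name} must have finite components, got {arr}")
    return arr


@dataclass
class Line3:
    """A 3D line through two distinct points ``p1`` and ``p2``.

    Points on the line are ``p1 + t * (p2 - p1)`` for scalar parameter ``t``;
    the direction is the (unnormalised) difference ``p2 - p1``.
    """

    p1: np.ndarray
    p2: np.ndarray

    def __post_init__(self) -> None:
        self.p1 = as_vec3(self.p1, "p1")
        self.p2 = as_vec3(self.p2, "p2")
        if float(np.linalg.norm(self.p2 - self.p1)) == 0.0:
            raise DegenerateLineError("line requires two distinct points")

    @property
    def direction(self) -> np.ndarray:
        return self.p2 - self.p1

    def point_at(self, t: float) -> np.ndarray:
        return self.p1 + t * self.direction

    def translated(self, v) -> "Line3":
        v = as_vec3(v, "translation")
        return Line3(self.p1 + v, self.p2 + v)


@dataclass
class Plane3:
    """A plane in Hessian normal form: points ``x`` with ``n . x = d``.

    ``n`` is a unit normal (enforced to 1e-12) and ``d`` the signed offset
    from the origin along ``n``, in cm.
    """

    n: np.ndarray
    d: float

    def __post_init__(self) -> None:
        self.n = as_vec3(self.n, "normal")
        if not np.isfinite(self.d):
            raise GeometryError("plane offset must be finite")
        nrm = np.linalg.norm(self.n)
        if nrm == 0.0:
            raise DegeneratePlaneError("plane normal must be nonzero")
        if abs(nrm - 1.0) > 1e-12:
            # normalise, keeping the plane's point set unchanged
            self.n = self.n / nrm
            self.d = self.d / nrm

    def signed_distance(self, q) -> float:
        q = as_vec3(q, "point")
        return float(self.n @ q - self.d)

    def contains(self, q, tol: float = 1e-9) -> bool:
        return abs(self.signed_distance(q)) <= tol


@dataclass
class LineIntersection:
    """Classification of a pair of 3D lines.

    status is one of ``point`` (unique intersection), ``skew``
    (non-parallel, non-intersecting), ``parallel`` or ``coincident``.
    ``t`` and ``u`` are the parameters of the mutually closest points on the
    first and second line; for status ``point`` these solve the simultaneous
    line equations and ``point`` is the (symmetrised) intersection.
    ``min_distance`` is the perpendicular gap between the lines in cm.
    """

    status: str
    point: np.ndarray | None = None
    t: float | None = None
    u: float | None = None
    min_distance: float = 0.0
    diagnostics: dict = field(default_factory=dict)


def lines_classify(L1: Line3, L2: Line3, tol: float = DEFAULT_TOL) -> LineIntersection:
    """Classify two 3D lines as intersecting, skew, parallel or coincident.

    Two non-parallel lines intersect iff the triple product of their
    directions' cross product with the offset between their anchor points
    vanishes; the test uses that triple product normalised by the magnitudes
    of the cross product and the offset, compared against ``tol``.

    For intersecting lines the closest-point parameters are obtained by a
    least-squares solve of the two parametric equations and the returned
    point is the midpoint of the two mutually closest points, which is robust
    to floating-point near-intersection.
    """
    if tol <= 0:
        raise GeometryError("tol must be positive")
    d1, d2 = L1.direction, L2.direction
    cross = np.cross(d1, d2)
    cross_norm = float(np.linalg.norm(cross))
    offset = L2.p1 - L1.p1
    off_norm = float(np.linalg.norm(offset))

    if cross_norm <= tol * float(np.linalg.norm(d1)) * float(np.linalg.norm(d2)):
        # parallel directions: coincident iff the offset lies along the line
        if off_norm == 0.0 or (
            float(np.linalg.norm(np.cross(offset, d1)))
            <= tol * off_norm * float(np.linalg.norm(d1))
        ):
            return LineIntersection(status="coincident")
        gap = float(
            np.linalg.norm(offset - (offset @ d1) / (d1 @ d1) * d1)
        )
        return LineIntersection(status="parallel", min_distance=gap)

    triple = float(offset @ cross)
    min_distance = abs(triple) / cross_norm
    normalised = 0.0 if off_norm == 0.0 else triple / (cross_norm * off_norm)

    # least-squares on p1_1 + t d1 = p1_2 + u d2
    A = np.column_stack([d1, -d2])
    sol, *_ = np.linalg.lstsq(A, offset, rcond=None)
    t, u = float(sol[0]), float(sol[1])
    q1, q2 = L1.point_at(t), L2.point_at(u)

    if abs(normalised) <= tol:
        return LineIntersection(
            status="point", point=(q1 + q2) / 2.0, t=t, u=u, min_distance=min_distance
        )
    return LineIntersection(status="skew", t=t, u=u, min_distance=min_distance)


def vertical_offset_condition(b, d, coplanar: bool, tol: float = DEFAULT_TOL) -> bool:
    """Existence condition for the intersection of two back-projected
    constraint lines, phrased on the image points ``b`` (left) and ``d``
    (right).

    In general the lines intersect iff ``y_b * z_d == y_d * z_b``; with
    coplanar image planes (equal z, horizontal epipolar lines) this reduces
    to equal vertical image coordinates ``y_b == y_d`` — zero vertical
    disparity between the two eyes' motion-vector endpoints.
    """
    b = as_vec3(b, "b")
    d = as_vec3(d, "d")
    if coplanar:
        scale = max(1.0, abs(b[1]), abs(d[1]))
        return abs(b[1] - d[1]) <= tol * scale
    lhs = b[1] * d[2]
    rhs = d[1] * b[2]
    scale = max(1.0, abs(lhs), abs(rhs))
    return abs(lhs - rhs) <= tol * scale


def plane_from_points(q1, q2, q3, tol: float = DEFAULT_TOL) -> Plane3:
    """Hessian-form plane through three non-collinear points."""
    q1 = as_vec3(q1, "q1")
    q2 = as_vec3(q2, "q2")
    q3 = as_vec3(q3, "q3")
    e1, e2 = q2 - q1, q3 - q1
    n = np.cross(e1, e2)
    nrm = np.linalg.norm(n)
    scale = np.linalg.norm(e1) * np.linalg.norm(e2)
    if scale == 0.0 or nrm <= tol * scale:
        raise DegeneratePlaneError("points are collinear or coincident")
    n = n / nrm
    return Plane3(n=n, d=n @ q1)


@dataclass
class PlaneIntersection:
    """Result of intersecting two planes: a ``line``, or ``parallel`` /
    ``coincident`` when the normals are (anti)parallel."""

    status: str
    line: Line3 | None = None


def planes_intersect(
    P_L: Plane3, P_R: Plane3, tol: float = DEFAULT_TOL
) -> PlaneIntersection:
    """Intersect two Hessian-form planes.

    When the unit normals are not (anti)parallel the intersection line has
    direction ``n_L x n_R`` and passes through the base point
    ``c_L n_L + c_R n_R`` where the scalars solve the two plane equations:

        c_L = (d_L - d_R (n_L.n_R)) / (1 - (n_L.n_R)^2)
        c_R = (d_R - d_L (n_L.n_R)) / (1 - (n_L.n_R)^2)

    Otherwise the planes are coincident iff their signed offsets agree (after
    aligning the normal sign), else parallel.
    """
    direction = np.cross(P_L.n, P_R.n)
    if np.linalg.norm(direction) <= tol:
        same_side = P_L.n @ P_R.n > 0
        d_other = P_R.d if same_side else -P_R.d
        status = "coincident" if abs(P_L.d - d_other) <= tol else "parallel"
        return PlaneIntersection(status=status)
    ndot = P_L.n @ P_R.n
    denom = 1.0 - ndot * ndot
    c_L = (P_L.d - P_R.d * ndot) / denom
    c_R = (P_R.d - P_L.d * ndot) / denom
    base = c_L * P_L.n + c_R * P_R.n
    u = direction / np.linalg.norm(direction)
    return PlaneIntersection(status="line", line=Line3(base, base + u))


def closest_point_on_line(L: Line3, q) -> tuple[np.ndarray, float]:
    """Foot of the perpendicular from ``q`` onto line ``L``.

    Returns ``(foot, lam)`` with ``foot = p1 + lam * (p2 - p1)``; the
    residual ``foot - q`` is orthogonal to the line direction, so ``foot`` is
    the (unique) nearest point of the line to ``q``.
    """
    q = as_vec3(q, "q")
    d = L.direction
    lam = ((q - L.p1) @ d) / (d @ d)
    return L.point_at(lam), lam
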