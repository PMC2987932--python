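"""Processing schemes for local binocular 3D motion.

Two default strategies resolve the 3D aperture problem for an oriented line
moving in depth:

* **Vector normal (VN)** — each eye's line motion constrains the 3D end
  position to a plane (nodal point + projected end line); the planes'
  intersection is a constraint line in 3D, and VN picks the point on it
  closest to the starting point: the slowest 3D motion satisfying both
  constraints.
* **Cyclopean average (CA)** — each eye first commits to its 2D default
  (the normal component of image motion); the two normal endpoints are
  averaged into a cyclopean endpoint and horizontal disparity, sampled on
  the end-position image lines at that height, is attached to recover depth.

Three established schemes are implemented as demonstrators of their failure
modes on the same stimuli:

* **IOVD** back-projects each eye's 2D normal endpoint to a constraint line;
  for a tilted line moving in depth the two lines are generically skew.
* **CDOT** tracks horizontal disparity at a fixed screen height over time and
  can only report motion in depth along the cyclopean line of sight.
* **JEMD** monitors (depth, binocular image speed) activations over a
  temporal window; mirrored front/back trajectories produce identical
  activation multisets.

``triangulate_point`` is the exact reference: intersecting the two eyes'
back-projected constraint lines for an unambiguous point feature recovers
the true velocity.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    DEFAULT_TOL,
    DegeneratePlaneError,
    GeometryError,
    Line3,
    as_vec3,
    closest_point_on_line,
    lines_classify,
    planes_intersect,
    plane_from_points,
)
from .spherical import SphericalMotion, to_spherical
from .stimulus import (
    EYES,
    LEFT,
    RIGHT,
    ImageLine,
    MotionEvent,
    ViewingGeometry,
    monocular_normal,
    project_line,
    project_point,
)

VN = "VN"
CA = "CA"
IOVD = "IOVD"
CDOT = "CDOT"
TRIANGULATION = "TRIANGULATION"
STRATEGIES = (VN, CA, IOVD, CDOT)


class TriangulationError(GeometryError):
    """Back-projected point-feature constraint lines failed to intersect."""


class DisparityDivergenceError(GeometryError):
    """Disparity-to-depth conversion diverged (i + eta <= 0)."""


@dataclass
class Prediction:
    """Outcome of one processing scheme on one motion event.

    status ``ok`` carries a 3D velocity (cm per unit time); ``skew`` means
    the scheme's constraint lines do not intersect (IOVD failure mode, with
    the perpendicular gap in ``diagnostics['min_distance']``); ``undefined``
    means the scheme's construction degenerates for this stimulus.
    """

    strategy: str
    status: str
    velocity: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.status == "ok") != (self.velocity is not None):
            raise ValueError("status 'ok' iff a velocity is present")
        if self.velocity is not None:
            self.velocity = as_vec3(self.velocity, "velocity")

    @property
    def spherical(self) -> SphericalMotion | None:
        return None if self.velocity is None else to_spherical(self.velocity)

    def to_dict(self) -> dict:
        rec: dict = {"strategy": self.strategy, "status": self.status}
        if self.velocity is not None:
            sph = self.spherical
            rec.update(
                vx=float(self.velocity[0]),
                vy=float(self.velocity[1]),
                vz=float(self.velocity[2]),
                azimuth_deg=sph.azimuth_deg,
                elevation_deg=sph.elevation_deg,
                speed=sph.speed,
            )
        for key in ("min_distance", "eta"):
            if key in self.diagnostics:
                rec[key] = float(self.diagnostics[key])
        return rec


def _lift(g: ViewingGeometry, xy: np.ndarray) -> np.ndarray:
    """Embed a 2D screen point at its 3D position on the plane z = D."""
    return np.array([xy[0], xy[1], g.D])


def _constraint_plane(g: ViewingGeometry, eye: str, end_line: Line3):
    """Plane through the eye's nodal point and the projected end line.

    Built in extended precision: for shallow tilts the left and right
    constraint planes are nearly coincident and their intersection amplifies
    rounding error by the reciprocal of the dihedral angle, so the VN chain
    carries the wider mantissa end to end.
    """
    p1 = np.asarray(end_line.p1, dtype=np.longdouble)
    p2 = np.asarray(end_line.p2, dtype=np.longdouble)
    q1 = _lift(g, project_point(g, eye, p1))
    q2 = _lift(g, project_point(g, eye, p2))
    return plane_from_points(np.asarray(g.nodal(eye), dtype=np.longdouble), q1, q2)


def vn_predict(e: MotionEvent, tol: float = DEFAULT_TOL) -> Prediction:
    """Vector-normal prediction: the slowest 3D velocity on the intersection
    of the two monocular constraint planes.

    The diagnostic ``constraint_line`` is that intersection line; the true
    3D end line lies in both planes by construction, so the constraint line
    coincides with it whenever the planes are in general position.
    """
    g = e.geometry
    try:
        planes = [_constraint_plane(g, eye, e.end_line) for eye in EYES]
    except (DegeneratePlaneError, GeometryError) as exc:
        return Prediction(VN, "undefined", diagnostics={"reason": str(exc)})
    res = planes_intersect(planes[0], planes[1], tol)
    if res.status != "line":
        return Prediction(VN, "undefined", diagnostics={"planes_status": res.status})
    foot, lam = closest_point_on_line(res.line, g.fixation)
    constraint = Line3(
        np.asarray(res.line.p1, dtype=float), np.asarray(res.line.p2, dtype=float)
    )
    return Prediction(
        VN,
        "ok",
        velocity=np.asarray(foot, dtype=float) - g.fixation,
        diagnostics={"constraint_line": constraint, "lambda": float(lam)},
    )


def _normal_endpoints(e: MotionEvent) -> dict[str, dict]:
    """Per-eye start/end image lines and the 2D normal-motion endpoint."""
    g = e.geometry
    out = {}
    for eye in EYES:
        start_img = project_line(g, eye, e.start_line)
        end_img = project_line(g, eye, e.end_line)
        normal = monocular_normal(start_img, end_img)
        out[eye] = {
            "start": start_img,
            "end": end_img,
            "endpoint": start_img.anchor + normal,
        }
    return out


def ca_predict(e: MotionEvent, tol: float = DEFAULT_TOL) -> Prediction:
    """Cyclopean-average prediction.

    The two eyes' normal-motion endpoints are averaged on the screen; the
    horizontal disparity ``eta`` between the end-position image lines is
    sampled at the cyclopean endpoint's height and split symmetrically into
    left/right screen points b and d, whose back-projected constraint lines
    intersect by construction (equal vertical coordinates on coplanar image
    planes).
    """
    g = e.geometry
    try:
        mono = _normal_endpoints(e)
    except GeometryError as exc:
        return Prediction(CA, "undefined", diagnostics={"reason": str(exc)})
    if mono[LEFT]["end"].is_horizontal() or mono[RIGHT]["end"].is_horizontal():
        return Prediction(
            CA, "undefined", diagnostics={"reason": "horizontal end image line"}
        )
    cyc = (mono[LEFT]["endpoint"] + mono[RIGHT]["endpoint"]) / 2.0
    eta = mono[LEFT]["end"].x_at(cyc[1]) - mono[RIGHT]["end"].x_at(cyc[1])
    b = _lift(g, cyc + np.array([eta / 2.0, 0.0]))
    d = _lift(g, cyc - np.array([eta / 2.0, 0.0]))
    res = lines_classify(Line3(g.nodal_left, b), Line3(g.nodal_right, d), tol)
    if res.status != "point":
        return Prediction(
            CA,
            "undefined",
            diagnostics={"eta": eta, "lines_status": res.status},
        )
    return Prediction(
        CA,
        "ok",
        velocity=res.point - g.fixation,
        diagnostics={"eta": eta, "cyclopean_endpoint": cyc},
    )


def iovd_predict(e: MotionEvent, tol: float = DEFAULT_TOL) -> Prediction:
    """Interocular-velocity-difference demonstrator.

    Each eye's 2D normal endpoint is back-projected to a constraint line
    through its nodal point; the prediction exists only when those lines
    intersect. For a tilted line moving in depth the lines are generically
    skew — the scheme's failure mode.
    """
    g = e.geometry
    try:
        mono = _normal_endpoints(e)
    except GeometryError as exc:
        return Prediction(IOVD, "undefined", diagnostics={"reason": str(exc)})
    lines = {
        eye: Line3(g.nodal(eye), _lift(g, mono[eye]["endpoint"])) for eye in EYES
    }
    res = lines_classify(lines[LEFT], lines[RIGHT], tol)
    if res.status == "point":
        return Prediction(
            IOVD,
            "ok",
            velocity=res.point - g.fixation,
            diagnostics={"min_distance": res.min_distance},
        )
    if res.status == "skew":
        return Prediction(IOVD, "skew", diagnostics={"min_distance": res.min_distance})
    return Prediction(IOVD, "undefined", diagnostics={"lines_status": res.status})


def cdot_predict(
    e: MotionEvent, probe_y: float = 0.0, tol: float = DEFAULT_TOL
) -> Prediction:
    """Changing-disparity-over-time demonstrator.

    Horizontal disparity ``eta(t)`` is sampled at screen height ``probe_y``
    on the start- and end-position image lines and converted to depth via
    ``z = i D / (i + eta)``; the reported velocity is confined to the
    cyclopean line of sight — lateral motion is unrecoverable by design.
    """
    g = e.geometry
    try:
        imgs = {
            eye: (project_line(g, eye, e.start_line), project_line(g, eye, e.end_line))
            for eye in EYES
        }
    except GeometryError as exc:
        return Prediction(CDOT, "undefined", diagnostics={"reason": str(exc)})
    if any(img.is_horizontal() for pair in imgs.values() for img in pair):
        return Prediction(
            CDOT, "undefined", diagnostics={"reason": "horizontal image line"}
        )

    def depth(sample_idx: int) -> tuple[float, float]:
        eta = imgs[LEFT][sample_idx].x_at(probe_y) - imgs[RIGHT][sample_idx].x_at(probe_y)
        if g.i + eta <= 0:
            raise DisparityDivergenceError(
                f"disparity eta={eta:g} puts the target at or beyond infinity"
            )
        return g.i * g.D / (g.i + eta), eta

    z0, eta0 = depth(0)
    z1, eta1 = depth(1)
    return Prediction(
        CDOT,
        "ok",
        velocity=np.array([0.0, 0.0, z1 - z0]),
        diagnostics={"eta_start": eta0, "eta_end": eta1, "probe_y": probe_y},
    )


def triangulate_point(
    g: ViewingGeometry, v_true, tol: float = DEFAULT_TOL
) -> Prediction:
    """Exact reference: recover the velocity of a point feature displaced
    from fixation by intersecting the two eyes' back-projected constraint
    lines through its images."""
    v_true = as_vec3(v_true, "v_true")
    F = g.fixation
    target = F + v_true
    if float(np.linalg.norm(v_true)) == 0.0:
        return Prediction(TRIANGULATION, "ok", velocity=np.zeros(3))
    lines = {
        eye: Line3(g.nodal(eye), _lift(g, project_point(g, eye, target)))
        for eye in EYES
    }
    res = lines_classify(lines[LEFT], lines[RIGHT], max(tol, 1e-9))
    if res.status != "point":
        raise TriangulationError(
            f"constraint lines classified as {res.status} for a consistent point"
        )
    return Prediction(TRIANGULATION, "ok", velocity=res.point - F)


@dataclass(frozen=True)
class JemdSignature:
    """Multiset of joint (depth, binocular image speed) activations.

    Each of the K trajectory steps contributes one element:
    (depth bin of the segment midpoint, left-eye image-speed bin, right-eye
    image-speed bin). The multiset discards temporal order — exactly the
    information a population read-out over a temporal window retains.
    """

    counts: tuple
    K: int
    depth_bin: float
    vel_bin: float

    def as_counter(self) -> Counter:
        return Counter(dict(self.counts))

    @property
    def size(self) -> int:
        return sum(n for _, n in self.counts)


def jemd_signature(
    g: ViewingGeometry,
    v,
    K: int = 10,
    depth_bin: float = 0.1,
    vel_bin: float = 0.01,
    start=None,
) -> JemdSignature:
    """Joint-encoding-of-motion-and-disparity demonstrator.

    The point trajectory ``start + (k/K) v`` (start defaults to fixation) is
    sampled at K+1 times; each of the K steps is recorded as the binned depth
    of its midpoint together with the binned magnitudes of the left- and
    right-eye image displacements. Trajectories traversing the same depth
    planes with the same binocular speeds — e.g. a trajectory and its time
    reversal — yield identical signatures.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    v = as_vec3(v, "v")
    start = g.fixation if start is None else as_vec3(start, "start")
    pts = [start + (k / K) * v for k in range(K + 1)]
    images = {
        eye: [project_point(g, eye, p) for p in pts] for eye in EYES
    }
    counter: Counter = Counter()
    for k in range(K):
        z_mid = (pts[k][2] + pts[k + 1][2]) / 2.0
        key = (
            int(np.round(z_mid / depth_bin)),
            int(np.round(np.linalg.norm(images[LEFT][k + 1] - images[LEFT][k]) / vel_bin)),
            int(np.round(np.linalg.norm(images[RIGHT][k + 1] - images[RIGHT][k]) / vel_bin)),
        )
        counter[key] += 1
    return JemdSignature(
        counts=tuple(sorted(counter.items())), K=K, depth_bin=depth_bin, vel_bin=vel_bin
    )
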