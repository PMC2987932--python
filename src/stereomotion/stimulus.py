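"""Binocular viewing geometry and ambiguous oriented-line motion stimuli.

Coordinate frame: x toward the right eye, y upward, z from the cyclopean
origin toward the fixation point. The two nodal points sit at (+-i/2, 0, 0),
fixation at (0, 0, D), and both eyes share a fronto-parallel projection
screen at z = D (coplanar image planes, so epipolar lines are horizontal).
All lengths in cm; a unit time step makes displacements equal velocities.

A stimulus is an oriented line through fixation whose ends are occluded (the
3D aperture problem): only its tilt, the orientation disparity between the
two eyes' projections, and its 3D trajectory are controlled. The line is
built so that its left/right image orientations are tilt +- disparity/2,
keeping the cyclopean orientation at the nominal tilt.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    GeometryError,
    Line3,
    as_vec3,
    plane_from_points,
    planes_intersect,
)
from .spherical import velocity_from_angles

LEFT = "left"
RIGHT = "right"
EYES = (LEFT, RIGHT)


class BehindEyeError(GeometryError):
    """A point at or behind the nodal-point plane cannot be projected."""


class DegenerateStimulusError(GeometryError):
    """The requested stimulus lies in an epipolar plane (or projects to a point)."""


@dataclass(frozen=True)
class ViewingGeometry:
    """Fixed binocular viewing geometry: interocular distance ``i`` and
    viewing distance ``D``, both cm, eyes verged on a fixation point straight
    ahead."""

    i: float = 6.5
    D: float = 57.0

    def __post_init__(self) -> None:
        if not (self.i > 0 and math.isfinite(self.i)):
            raise ValueError("interocular distance i must be positive")
        if not (self.D > 0 and math.isfinite(self.D)):
            raise ValueError("viewing distance D must be positive")

    @property
    def nodal_left(self) -> np.ndarray:
        return np.array([-self.i / 2.0, 0.0, 0.0])

    @property
    def nodal_right(self) -> np.ndarray:
        return np.array([self.i / 2.0, 0.0, 0.0])

    @property
    def cyclopean_origin(self) -> np.ndarray:
        return np.zeros(3)

    @property
    def fixation(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.D])

    def nodal(self, eye: str) -> np.ndarray:
        if eye == LEFT:
            return self.nodal_left
        if eye == RIGHT:
            return self.nodal_right
        raise ValueError(f"eye must be 'left' or 'right', got {eye!r}")

    def to_dict(self) -> dict:
        return {"i_cm": self.i, "D_cm": self.D}

    @classmethod
    def from_dict(cls, d: dict) -> "ViewingGeometry":
        return cls(i=float(d.get("i_cm", 6.5)), D=float(d.get("D_cm", 57.0)))


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of one oriented-line motion event.

    tilt_deg: cyclopean line orientation from horizontal, in (0, 180) —
        horizontal lines lie in an epipolar plane and are excluded.
    orientation_disparity_deg: left minus right image orientation; nonzero
        values slant the line in depth.
    azimuth_deg / elevation_deg / speed_cm: the 3D trajectory (see
        :mod:`stereomotion.spherical` for the angle convention).
    """

    tilt_deg: float = 45.0
    orientation_disparity_deg: float = 0.0
    azimuth_deg: float = 0.0
    elevation_deg: float = 0.0
    speed_cm: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.tilt_deg < 180.0):
            raise ValueError("tilt_deg must lie strictly between 0 and 180")
        if self.speed_cm < 0:
            raise ValueError("speed_cm must be >= 0")

    def with_disparity(self, delta_deg: float) -> "StimulusSpec":
        return replace(self, orientation_disparity_deg=float(delta_deg))

    def to_dict(self) -> dict:
        return {
            "tilt_deg": self.tilt_deg,
            "orientation_disparity_deg": self.orientation_disparity_deg,
            "azimuth_deg": self.azimuth_deg,
            "elevation_deg": self.elevation_deg,
            "speed_cm": self.speed_cm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        known = {
            k: float(d[k])
            for k in (
                "tilt_deg",
                "orientation_disparity_deg",
                "azimuth_deg",
                "elevation_deg",
                "speed_cm",
            )
            if k in d
        }
        return cls(**known)


@dataclass
class ImageLine:
    """A projected line on the screen plane z = D: a 2D anchor point (cm)
    plus an orientation in degrees from horizontal, folded into [0, 180)."""

    anchor: np.ndarray
    orientation_deg: float

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=float)
        if self.anchor.shape != (2,) or not np.all(np.isfinite(self.anchor)):
            raise GeometryError("ImageLine anchor must be a finite 2-vector")
        self.orientation_deg = float(self.orientation_deg) % 180.0

    @property
    def direction(self) -> np.ndarray:
        th = math.radians(self.orientation_deg)
        return np.array([math.cos(th), math.sin(th)])

    def is_horizontal(self, tol: float = 1e-12) -> bool:
        return abs(math.sin(math.radians(self.orientation_deg))) <= tol

    def x_at(self, y: float) -> float:
        """Horizontal coordinate where the line crosses height ``y``."""
        if self.is_horizontal():
            raise GeometryError("horizontal image line has no unique x at a given y")
        w = self.direction
        t = (float(y) - self.anchor[1]) / w[1]
        return float(self.anchor[0] + t * w[0])

    def foot_from(self, q) -> np.ndarray:
        """Foot of the perpendicular from 2D point ``q`` onto this line."""
        q = np.asarray(q, dtype=float)
        w = self.direction
        return self.anchor + float((q - self.anchor) @ w) * w


@dataclass
class MotionEvent:
    """An oriented line through fixation plus its displacement over one unit
    time step: ``end_line`` is ``start_line`` translated by ``velocity``."""

    geometry: ViewingGeometry
    start_line: Line3
    velocity: np.ndarray
    end_line: Line3 = field(init=False)

    def __post_init__(self) -> None:
        self.velocity = as_vec3(self.velocity, "velocity")
        self.end_line = self.start_line.translated(self.velocity)


def project_point(g: ViewingGeometry, eye: str, P, eps: float = 1e-9) -> np.ndarray:
    """Central projection of a 3D point onto the screen z = D through the
    eye's nodal point; returns the 2D screen coordinates (cm).

    A point on the screen projects to itself; points at or behind the
    nodal-point plane (z <= eps) cannot be imaged.
    """
    P = as_vec3(P, "P")
    if P[2] <= eps:
        raise BehindEyeError(f"point with z={P[2]:g} is behind the eye")
    n = g.nodal(eye)
    img = n + (P - n) * (g.D / P[2])
    return img[:2]


def project_line(g: ViewingGeometry, eye: str, L: Line3) -> ImageLine:
    """Project a 3D line into one eye; the image is the line through the two
    projected defining points."""
    a = project_point(g, eye, L.p1)
    b = project_point(g, eye, L.p2)
    d = b - a
    if float(np.hypot(d[0], d[1])) <= 1e-12:
        raise DegenerateStimulusError("line projects to a single image point")
    return ImageLine(anchor=a, orientation_deg=math.degrees(math.atan2(d[1], d[0])))


def monocular_normal(start_img: ImageLine, end_img: ImageLine) -> np.ndarray:
    """Default 2D motion percept under the aperture problem: the component
    of the image displacement normal to the moving line, i.e. the vector
    from the start anchor to the foot of its perpendicular on the end line.
    """
    foot = end_img.foot_from(start_img.anchor)
    return foot - start_img.anchor


def build_line_from_orientations(
    g: ViewingGeometry, theta_left_deg: float, theta_right_deg: float
) -> Line3:
    """The 3D line through fixation whose left/right screen projections have
    the given orientations.

    Each image orientation back-projects to a plane through the eye's nodal
    point containing the image line through the screen origin; the stimulus
    line is the intersection of the two planes. Both image lines horizontal
    (the epipolar plane y = 0) leaves the planes coincident and the stimulus
    undefined.
    """
    F = g.fixation

    def back_plane(nodal: np.ndarray, theta_deg: float):
        th = math.radians(theta_deg)
        screen_dir = np.array([math.cos(th), math.sin(th), 0.0])
        return plane_from_points(nodal, F, F + screen_dir)

    res = planes_intersect(
        back_plane(g.nodal_left, theta_left_deg),
        back_plane(g.nodal_right, theta_right_deg),
    )
    if res.status != "line":
        raise DegenerateStimulusError(
            "image orientations back-project to coincident planes "
            "(line lies in an epipolar plane)"
        )
    direction = res.line.direction
    direction = direction / float(np.linalg.norm(direction))
    if direction[1] < 0:
        direction = -direction
    if abs(direction[1]) <= 1e-12:
        raise DegenerateStimulusError("stimulus line lies in an epipolar plane")
    return Line3(F, F + direction)


def make_motion_event(g: ViewingGeometry, spec: StimulusSpec) -> MotionEvent:
    """Synthesize a motion event from a stimulus specification.

    The start line's image orientations are tilt +- disparity/2 (symmetric
    split keeps the cyclopean orientation at the nominal tilt); the velocity
    comes from the spherical trajectory parameters; the end line is the start
    line displaced rigidly by that velocity.
    """
    theta_left = (spec.tilt_deg + spec.orientation_disparity_deg / 2.0) % 180.0
    theta_right = (spec.tilt_deg - spec.orientation_disparity_deg / 2.0) % 180.0
    start = build_line_from_orientations(g, theta_left, theta_right)
    v = velocity_from_angles(spec.azimuth_deg, spec.elevation_deg, spec.speed_cm)
    return MotionEvent(geometry=g, start_line=start, velocity=v)
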