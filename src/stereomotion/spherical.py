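"""Cartesian <-> spherical transforms for 3D motion vectors.

Convention (anchored to the viewing frame: x toward the right eye, y upward,
z from the cyclopean origin toward fixation):

* azimuth ``alpha`` and elevation ``beta`` of 0 deg denote a horizontal,
  fronto-parallel trajectory to the left, i.e. the -x direction;
* positive azimuth rotates the trajectory toward the observer (-z), so a
  trajectory "to the front and left" has positive azimuth;
* positive elevation rotates upward (+y);
* speed is the Euclidean norm of the velocity vector, cm per unit time.

A zero-speed motion reports azimuth and elevation of 0 by convention.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import as_vec3


@dataclass(frozen=True)
class SphericalMotion:
    """3D motion direction and speed in spherical form (degrees, cm/unit time)."""

    azimuth_deg: float
    elevation_deg: float
    speed: float

    def __post_init__(self) -> None:
        if not (self.speed >= 0.0 and math.isfinite(self.speed)):
            raise ValueError("speed must be finite and >= 0")


def to_spherical(v) -> SphericalMotion:
    """Azimuth, elevation and speed of a cartesian velocity vector."""
    v = as_vec3(v, "velocity")
    speed = float(np.linalg.norm(v))
    if speed == 0.0:
        return SphericalMotion(0.0, 0.0, 0.0)
    horizontal = math.hypot(v[0], v[2])
    if horizontal == 0.0:
        azimuth = 0.0  # purely vertical motion: azimuth undefined, report 0
    else:
        azimuth = math.degrees(math.atan2(-v[2], -v[0]))
        if azimuth <= -180.0:  # fold the branch cut onto (-180, 180]
            azimuth += 360.0
    elevation = math.degrees(math.atan2(v[1], horizontal))
    return SphericalMotion(azimuth, elevation, speed)


def from_spherical(s: SphericalMotion) -> np.ndarray:
    """Cartesian velocity vector of a spherical motion (inverse of
    :func:`to_spherical` for positive speed)."""
    a = math.radians(s.azimuth_deg)
    b = math.radians(s.elevation_deg)
    return s.speed * np.array(
        [-math.cos(b) * math.cos(a), math.sin(b), -math.cos(b) * math.sin(a)]
    )


def velocity_from_angles(azimuth_deg: float, elevation_deg: float, speed: float) -> np.ndarray:
    """Convenience wrapper building the cartesian velocity directly."""
    return from_spherical(SphericalMotion(azimuth_deg, elevation_deg, speed))
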