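"""Coordinate systems, head rotations and angular arithmetic.

Two direction parameterizations are used throughout:

* **Spherical**: azimuth in degrees in ``[-180, 180)``, 0 = straight ahead,
  positive toward the listener's *left*; elevation in ``[-90, 90]``,
  positive up.
* **Interaural-polar**: lateral angle in ``[-90, 90]``, positive left,
  measuring displacement from the median plane; polar angle in
  ``[-90, 270)`` measuring position within the sagittal plane
  (0 = front at eye level, 90 = overhead, 180 = rear).  All directions
  sharing one lateral angle lie on one "cone of confusion".

The head-fixed Cartesian frame is right-handed with x pointing front,
y left, z up.  Head orientations are yaw/pitch/roll in degrees, composed
in that order about the body axes (yaw about z, positive left; pitch about
the interaural axis, positive up; roll about x).

All public functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DirectionSph",
    "DirectionIP",
    "HeadOrientation",
    "sph_to_unit",
    "unit_to_sph",
    "sph_to_interaural",
    "interaural_to_sph",
    "rotation_matrix",
    "head_relative_direction",
    "angular_distance",
    "wrap_degrees",
    "wrap_polar",
]


def wrap_degrees(angle_deg, lo: float = -180.0):
    """Wrap angles into the half-open interval ``[lo, lo + 360)``."""
    return (np.asarray(angle_deg, dtype=float) - lo) % 360.0 + lo


def wrap_polar(polar_deg):
    """Wrap polar angles into ``[-90, 270)``."""
    return wrap_degrees(polar_deg, lo=-90.0)


@dataclass(frozen=True)
class DirectionSph:
    """A sound direction in spherical coordinates (degrees)."""

    azimuth_deg: float
    elevation_deg: float

    def __post_init__(self):
        object.__setattr__(
            self, "azimuth_deg", float(wrap_degrees(self.azimuth_deg))
        )
        if not -90.0 <= self.elevation_deg <= 90.0:
            raise ValueError(f"elevation {self.elevation_deg} outside [-90, 90]")
        object.__setattr__(self, "elevation_deg", float(self.elevation_deg))

    def to_unit(self) -> np.ndarray:
        return np.array(sph_to_unit(self.azimuth_deg, self.elevation_deg))

    def to_interaural(self) -> "DirectionIP":
        lat, pol = sph_to_interaural(self.azimuth_deg, self.elevation_deg)
        return DirectionIP(float(lat), float(pol))


@dataclass(frozen=True)
class DirectionIP:
    """A sound direction in interaural-polar coordinates (degrees)."""

    lateral_deg: float
    polar_deg: float

    def __post_init__(self):
        if not -90.0 <= self.lateral_deg <= 90.0:
            raise ValueError(f"lateral {self.lateral_deg} outside [-90, 90]")
        object.__setattr__(self, "polar_deg", float(wrap_polar(self.polar_deg)))

    def to_sph(self) -> DirectionSph:
        az, el = interaural_to_sph(self.lateral_deg, self.polar_deg)
        return DirectionSph(float(az), float(el))


@dataclass(frozen=True)
class HeadOrientation:
    """Head orientation as yaw → pitch → roll (degrees) about body axes."""

    yaw_deg: float = 0.0
    pitch_deg: float = 0.0
    roll_deg: float = 0.0

    def matrix(self) -> np.ndarray:
        """World-from-head rotation matrix."""
        return rotation_matrix(self.yaw_deg, self.pitch_deg, self.roll_deg)

    def inverse(self) -> "HeadOrientation":
        """Orientation whose matrix is the transpose of this one's.

        Composition order is fixed (yaw→pitch→roll), so the inverse is
        returned via the matrix rather than by negating angles.
        """
        return orientation_from_matrix(self.matrix().T)


def sph_to_unit(azimuth_deg, elevation_deg):
    """Spherical direction → unit vector (x front, y left, z up)."""
    az = np.deg2rad(np.asarray(azimuth_deg, dtype=float))
    el = np.deg2rad(np.asarray(elevation_deg, dtype=float))
    return (
        np.cos(el) * np.cos(az),
        np.cos(el) * np.sin(az),
        np.sin(el),
    )


def unit_to_sph(x, y, z):
    """Unit vector → (azimuth, elevation) in degrees."""
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    az = np.rad2deg(np.arctan2(y, x))
    el = np.rad2deg(np.arcsin(np.clip(z, -1.0, 1.0)))
    return wrap_degrees(az), el


def sph_to_interaural(azimuth_deg, elevation_deg):
    """Spherical → interaural-polar coordinates (degrees).

    lateral = asin(y), polar = atan2(z, x) of the unit vector, with the
    polar angle wrapped to ``[-90, 270)``.
    """
    x, y, z = sph_to_unit(azimuth_deg, elevation_deg)
    lat = np.rad2deg(np.arcsin(np.clip(y, -1.0, 1.0)))
    pol = wrap_polar(np.rad2deg(np.arctan2(z, x)))
    # On the interaural axis the sagittal plane degenerates; pin polar to 0.
    degenerate = (np.abs(np.asarray(x)) < 1e-15) & (np.abs(np.asarray(z)) < 1e-15)
    pol = np.where(degenerate, 0.0, pol)
    if np.ndim(azimuth_deg) == 0 and np.ndim(elevation_deg) == 0:
        return float(lat), float(pol)
    return lat, pol


def interaural_to_sph(lateral_deg, polar_deg):
    """Interaural-polar → spherical coordinates (degrees); exact inverse."""
    lat = np.deg2rad(np.asarray(lateral_deg, dtype=float))
    pol = np.deg2rad(np.asarray(polar_deg, dtype=float))
    y = np.sin(lat)
    x = np.cos(lat) * np.cos(pol)
    z = np.cos(lat) * np.sin(pol)
    az, el = unit_to_sph(x, y, z)
    if np.ndim(lateral_deg) == 0 and np.ndim(polar_deg) == 0:
        return float(az), float(el)
    return az, el


def _rz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry_pitch(a):
    # Positive pitch tilts the head's front axis upward.
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])


def _rx(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rotation_matrix(yaw_deg: float, pitch_deg: float, roll_deg: float = 0.0) -> np.ndarray:
    """World-from-head rotation for yaw → pitch → roll (degrees)."""
    return (
        _rz(np.deg2rad(yaw_deg))
        @ _ry_pitch(np.deg2rad(pitch_deg))
        @ _rx(np.deg2rad(roll_deg))
    )


def orientation_from_matrix(m: np.ndarray) -> HeadOrientation:
    """Factor a rotation matrix back into yaw/pitch/roll angles."""
    # m @ e_x is the head-front axis in world coordinates.
    front = m[:, 0]
    pitch = np.arcsin(np.clip(front[2], -1.0, 1.0))
    yaw = np.arctan2(front[1], front[0])
    m_nr = _rz(yaw) @ _ry_pitch(pitch)
    # Residual rotation about the front axis is the roll.
    resid = m_nr.T @ m
    roll = np.arctan2(resid[2, 1], resid[1, 1])
    return HeadOrientation(
        float(np.rad2deg(yaw)), float(np.rad2deg(pitch)), float(np.rad2deg(roll))
    )


def head_relative_direction(d: DirectionSph, o: HeadOrientation) -> DirectionSph:
    """Direction of a world-fixed source expressed in the rotated head frame."""
    v = d.to_unit()
    vh = o.matrix().T @ v
    az, el = unit_to_sph(*vh)
    return DirectionSph(float(az), float(el))


def angular_distance(az1, el1, az2=None, el2=None):
    """Great-circle angle between directions, in degrees in ``[0, 180]``.

    Accepts either two :class:`DirectionSph` objects or four angle arrays
    ``(az1, el1, az2, el2)``.
    """
    if isinstance(az1, DirectionSph):
        d1, d2 = az1, el1
        az1, el1 = d1.azimuth_deg, d1.elevation_deg
        az2, el2 = d2.azimuth_deg, d2.elevation_deg
    v1 = np.stack(np.broadcast_arrays(*sph_to_unit(az1, el1)), axis=-1)
    v2 = np.stack(np.broadcast_arrays(*sph_to_unit(az2, el2)), axis=-1)
    # atan2 of cross/dot keeps full precision for near-0 and near-180 angles
    cross = np.linalg.norm(np.cross(v1, v2), axis=-1)
    dot = np.sum(v1 * v2, axis=-1)
    out = np.rad2deg(np.arctan2(cross, dot))
    return float(out) if np.ndim(out) == 0 else out
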