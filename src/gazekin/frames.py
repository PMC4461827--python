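"""Conversions among screen targets, direction vectors, angular positions,
and retinal error.

The reference condition is the straight-ahead configuration: eye, head and
space frames coincide, and the reference eye/head/gaze vectors are all
``[1, 0, 0]`` (forward).  A direction is described either as a unit 3-vector
or as a 2-D angular position ``(gamma, eta)``: azimuth ``gamma`` (positive
toward ``+y``) and elevation ``eta`` (positive toward ``+z``), both in
degrees, with ``v = [cos eta cos gamma, cos eta sin gamma, sin eta]``.

Screen geometry assumes a flat screen orthogonal to the forward axis at
distance ``t`` (cm) from the eye; screen offsets ``(a, b)`` are measured in
cm from the screen center along ``+y`` and ``+z``.  The default conversion
between gaze direction and screen point is the self-consistent central
projection ``a = t·g_y/g_x``; the simpler small-angle form ``a = t·g_y``
(which is not the exact inverse of the direction-from-screen formula) is
available behind a flag for comparison.

Retinal error is the desired gaze direction expressed in the initial eye
frame, ``g_RE = G_i⁻¹ · g_d``; it equals ``[1, 0, 0]`` exactly when the
target is already foveated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rotation import check_rotation

__all__ = [
    "AngularPosition2D",
    "ScreenTarget",
    "RetinalErrorAngles",
    "REFERENCE_DIRECTION",
    "dir_from_angles",
    "angles_from_dir",
    "gaze_from_screen_target",
    "screen_target_from_gaze",
    "retinal_error_vector",
    "desired_gaze_from_retinal_error",
    "retinal_error_angles",
    "retinal_eccentricity_deg",
    "angle_between_deg",
]

#: Forward unit vector shared by the reference eye, head and gaze vectors.
REFERENCE_DIRECTION = np.array([1.0, 0.0, 0.0])

#: Default eye-to-screen distance (cm).
DEFAULT_SCREEN_DISTANCE_CM = 100.0


class OutOfHemisphereError(ValueError):
    """Direction leaves the front hemisphere (x-component not positive)."""


class DegenerateAzimuthError(ValueError):
    """Retinal-error azimuth undefined at a pole of the polar convention."""


@dataclass(frozen=True)
class AngularPosition2D:
    """2-D angular position: azimuth ``gamma`` and elevation ``eta`` (deg),
    both restricted to the open interval (−90, 90)."""

    gamma: float
    eta: float

    def __post_init__(self) -> None:
        if not (abs(self.gamma) < 90.0 and abs(self.eta) < 90.0):
            raise OutOfHemisphereError(
                "angular position must lie strictly inside the front "
                f"hemisphere; got gamma={self.gamma}, eta={self.eta}"
            )


@dataclass(frozen=True)
class ScreenTarget:
    """Target on a flat screen: horizontal offset ``a`` (cm, +left),
    vertical offset ``b`` (cm, +up), eye-to-screen distance ``t`` (cm)."""

    a: float
    b: float
    t: float = DEFAULT_SCREEN_DISTANCE_CM

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError(f"screen distance t must be positive; got {self.t}")


@dataclass(frozen=True)
class RetinalErrorAngles:
    """Retinal error in polar form: ``polar`` measured from the retinal
    z-axis, ``azimuth`` within the transverse plane (deg)."""

    polar: float
    azimuth: float


def dir_from_angles(p: AngularPosition2D) -> np.ndarray:
    g = np.deg2rad(p.gamma)
    e = np.deg2rad(p.eta)
    return np.array([np.cos(e) * np.cos(g), np.cos(e) * np.sin(g), np.sin(e)])


def angles_from_dir(v: np.ndarray) -> AngularPosition2D:
    v = _unit(v)
    if v[0] <= 0:
        raise OutOfHemisphereError(
            "direction leaves the front hemisphere (x-component <= 0)"
        )
    eta = np.arcsin(np.clip(v[2], -1.0, 1.0))
    gamma = np.arctan2(v[1], v[0])
    return AngularPosition2D(float(np.rad2deg(gamma)), float(np.rad2deg(eta)))


def gaze_from_screen_target(target: ScreenTarget) -> np.ndarray:
    v = np.array([target.t, target.a, target.b])
    return v / np.linalg.norm(v)


def screen_target_from_gaze(
    g: np.ndarray, t: float = DEFAULT_SCREEN_DISTANCE_CM, *, literal: bool = False
) -> ScreenTarget:
    """Screen point where gaze direction ``g`` intersects the screen.

    ``literal=True`` selects the small-angle form ``(t·g_y, t·g_z)`` instead
    of the central projection; it is not the exact inverse of
    :func:`gaze_from_screen_target` and exists only for comparison.
    """
    g = _unit(g)
    if g[0] <= 0:
        raise OutOfHemisphereError("gaze points behind the screen (g_x <= 0)")
    if literal:
        return ScreenTarget(t * g[1], t * g[2], t)
    return ScreenTarget(t * g[1] / g[0], t * g[2] / g[0], t)


def retinal_error_vector(G_i: np.ndarray, g_d: np.ndarray) -> np.ndarray:
    """Desired gaze direction in initial eye coordinates, ``G_i⁻¹ · g_d``."""
    G_i = check_rotation(G_i)
    return G_i.T @ _unit(g_d)


def desired_gaze_from_retinal_error(G_i: np.ndarray, g_RE: np.ndarray) -> np.ndarray:
    """Space-frame target direction for a given retinal error: ``G_i · g_RE``."""
    G_i = check_rotation(G_i)
    return G_i @ _unit(g_RE)


def retinal_error_angles(g_RE: np.ndarray) -> RetinalErrorAngles:
    """Polar-form retinal error.

    ``polar = acos(g_z)``; the azimuth uses two-argument ``atan2(g_x, g_y)``
    so its sign is recovered (a plain arccos would lose it).  Undefined at
    the poles ``g = ±[0, 0, 1]``.
    """
    g = _unit(g_RE)
    polar = np.arccos(np.clip(g[2], -1.0, 1.0))
    if np.sin(polar) < 1e-12:
        raise DegenerateAzimuthError("azimuth undefined at the retinal pole")
    azimuth = np.arctan2(g[0], g[1])
    return RetinalErrorAngles(float(np.rad2deg(polar)), float(np.rad2deg(azimuth)))


def retinal_eccentricity_deg(g_RE: np.ndarray) -> float:
    """Angular distance of the retinal image from the fovea, in degrees."""
    return angle_between_deg(g_RE, REFERENCE_DIRECTION)


def angle_between_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    """Unsigned angle between two vectors, in degrees."""
    v1, v2 = _unit(v1), _unit(v2)
    # atan2 form is accurate near 0 and 180 deg where arccos loses precision
    return float(np.rad2deg(np.arctan2(np.linalg.norm(np.cross(v1, v2)), np.dot(v1, v2))))


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if not np.isfinite(n) or n < 1e-12:
        raise ValueError("cannot normalize a zero or non-finite vector")
    return v / n
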