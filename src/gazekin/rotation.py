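"""Exact 3-D rotation algebra used throughout the package.

Conventions
-----------
* Right-handed space frame: ``x`` forward (the reference gaze direction),
  ``y`` left, ``z`` up, so that ``x × y = z``.
* All rotations are *active*: an orientation matrix maps reference-condition
  vectors onto current vectors.
* Rotation matrices are plain ``(3, 3)`` :class:`numpy.ndarray` objects;
  helpers below validate orthonormality (``R Rᵀ = I``, ``det R = +1``).
* Angles are in **degrees** at every public interface and in radians only
  inside closed formulas.  Rotation *vectors* (axis scaled by magnitude) are
  kept in radians because they are added and subtracted as displacement
  commands; torsion metrics derived from them are reported in degrees.

Two torsion metrics recur in gaze kinematics and are defined here once:

* *Listing torsion* of an eye-in-head orientation is the forward-axis
  (``x``) component of its rotation vector.  It is zero exactly when the
  rotation axis lies in Listing's plane (the ``y``–``z`` plane).
* *Fick torsion* of a head orientation is the third Fick angle ``psi`` — the
  residual rotation about the forward axis after the vertical-axis and
  horizontal-axis rotations of a Fick gimbal have been accounted for.

Positive torsion is counterclockwise about ``+x`` by the right-hand rule
(seen from behind the head looking forward); this is a sign convention of
the package, not a physiological claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AxisAngle",
    "FickAngles",
    "rot_about_axis",
    "axis_angle_of",
    "rotvec_of",
    "rotation_from_rotvec",
    "fick_matrix",
    "fick_angles_of",
    "compose",
    "invert",
    "orthonormalize",
    "is_rotation",
    "check_rotation",
    "listing_torsion_deg",
    "fick_torsion_deg",
    "identity",
    "rot_x",
    "rot_y",
    "rot_z",
]

#: Orthonormality / determinant tolerance for accepting a matrix as a rotation.
ORTHO_TOL = 1e-9

_EPS_ANGLE = 1e-9  # below this magnitude (rad) a rotation counts as identity


class InvalidAxisError(ValueError):
    """Axis supplied to :func:`rot_about_axis` is not a unit vector."""


class GimbalLockError(ValueError):
    """Fick decomposition undefined: elevation magnitude reaches 90 deg."""


class NotARotationError(ValueError):
    """Matrix fails the orthonormal / determinant +1 test."""


@dataclass(frozen=True)
class AxisAngle:
    """Axis–angle form of a rotation.

    ``axis`` is a unit 3-vector; ``angle_deg`` lies in ``[0, 180]``.
    """

    axis: np.ndarray
    angle_deg: float


@dataclass(frozen=True)
class FickAngles:
    """Fick-gimbal decomposition of an orientation, in degrees.

    ``theta``: rotation about the space-vertical axis (``z``),
    ``phi``: rotation about the interim horizontal axis (``y``),
    ``psi``: torsional rotation about the forward axis (``x``).
    The matrix is the composition ``Rz(theta) · Ry(phi) · Rx(psi)``.
    ``|phi| < 90`` is required (gimbal lock excluded).
    """

    theta: float
    phi: float
    psi: float = 0.0


def identity() -> np.ndarray:
    return np.eye(3)


def is_rotation(R: np.ndarray, tol: float = ORTHO_TOL) -> bool:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        return False
    if np.linalg.norm(R @ R.T - np.eye(3)) > tol:
        return False
    return bool(abs(np.linalg.det(R) - 1.0) <= tol)


def check_rotation(R: np.ndarray, tol: float = ORTHO_TOL) -> np.ndarray:
    """Validate ``R`` and return it as a float array; raise otherwise."""
    R = np.asarray(R, dtype=float)
    if not is_rotation(R, tol):
        raise NotARotationError(
            "matrix is not orthonormal with determinant +1 "
            f"(tolerance {tol:g})"
        )
    return R


def rot_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Active right-handed rotation by ``angle_deg`` about unit ``axis``.

    Rodrigues' formula ``R = I cosτ + (1 − cosτ) u uᵀ + [u]× sinτ``.
    """
    u = np.asarray(axis, dtype=float)
    if u.shape != (3,) or not np.all(np.isfinite(u)) or abs(np.linalg.norm(u) - 1.0) > 1e-9:
        raise InvalidAxisError("rotation axis must be a finite unit 3-vector")
    tau = np.deg2rad(angle_deg)
    c, s = np.cos(tau), np.sin(tau)
    ux, uy, uz = u
    cross = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    return c * np.eye(3) + (1.0 - c) * np.outer(u, u) + s * cross


def rot_x(angle_deg: float) -> np.ndarray:
    return rot_about_axis(np.array([1.0, 0.0, 0.0]), angle_deg)


def rot_y(angle_deg: float) -> np.ndarray:
    return rot_about_axis(np.array([0.0, 1.0, 0.0]), angle_deg)


def rot_z(angle_deg: float) -> np.ndarray:
    return rot_about_axis(np.array([0.0, 0.0, 1.0]), angle_deg)


def axis_angle_of(R: np.ndarray) -> AxisAngle:
    """Magnitude/axis decomposition with the angle in ``[0, 180]`` deg.

    Degenerate branches are resolved deterministically: the identity maps to
    axis ``[0, 0, 1]`` with zero angle; near 180 deg the axis comes from the
    dominant eigenvector of ``(R + Rᵀ + (1 − tr R) I) / 2`` with the sign
    fixed so its largest-magnitude component is positive.
    """
    R = check_rotation(R)
    skew = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    # atan2 of (2 sin tau, 2 cos tau + 1) stays well-conditioned at both the
    # identity (where arccos of the trace loses half the digits) and near pi
    s2 = np.linalg.norm(skew)
    c2 = np.trace(R) - 1.0
    tau = np.arctan2(s2, c2)
    if tau < _EPS_ANGLE:
        return AxisAngle(np.array([0.0, 0.0, 1.0]), 0.0)
    if np.pi - tau > 1e-6:
        u = skew / s2
    else:
        # Near a half-turn the skew part vanishes; recover the axis from the
        # symmetric part: u uᵀ = (R + I) / 2 at exactly 180 deg.
        B = (R + np.eye(3)) / 2.0
        k = int(np.argmax(np.diag(B)))
        u = B[:, k] / np.sqrt(B[k, k])
        i = int(np.argmax(np.abs(u)))
        if u[i] < 0:
            u = -u
        # keep consistency with the skew part when it is not exactly zero
        if np.linalg.norm(skew) > 1e-12 and np.dot(u, skew) < 0:
            u = -u
    u = u / np.linalg.norm(u)
    return AxisAngle(u, float(np.rad2deg(tau)))


def rotvec_of(R: np.ndarray) -> np.ndarray:
    """Rotation vector ``u · τ`` (radians), ``‖r‖ ≤ π``.

    Component ``r[0]`` (forward axis) is the torsional coordinate, ``r[1]``
    the vertical-rotation coordinate, ``r[2]`` the horizontal-rotation
    coordinate.
    """
    aa = axis_angle_of(R)
    return aa.axis * np.deg2rad(aa.angle_deg)


def rotation_from_rotvec(r: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rotvec_of`."""
    r = np.asarray(r, dtype=float)
    tau = np.linalg.norm(r)
    if tau < _EPS_ANGLE:
        return np.eye(3)
    return rot_about_axis(r / tau, np.rad2deg(tau))


def fick_matrix(angles: FickAngles) -> np.ndarray:
    """Rotation matrix of a Fick-gimbal angle triple.

    Composition order ``Rz(theta) · Ry(phi) · Rx(psi)``: vertical-axis
    rotation first, then the interim horizontal axis, then torsion.  With
    ``psi = 0`` the third row is ``[−sin phi, 0, cos phi]``.
    """
    if abs(angles.phi) >= 90.0:
        raise GimbalLockError("Fick elevation |phi| must be < 90 deg")
    return rot_z(angles.theta) @ rot_y(angles.phi) @ rot_x(angles.psi)


def fick_angles_of(R: np.ndarray) -> FickAngles:
    """Recover Fick angles (deg) from a rotation matrix.

    ``phi = asin(−R[2,0])``, ``theta = atan2(R[1,0], R[0,0])``,
    ``psi = atan2(R[2,1], R[2,2])``.  Raises at gimbal lock.
    """
    R = check_rotation(R)
    s_phi = -R[2, 0]
    if abs(s_phi) >= 1.0 - 1e-12:
        raise GimbalLockError("Fick decomposition undefined at |phi| = 90 deg")
    phi = np.arcsin(s_phi)
    theta = np.arctan2(R[1, 0], R[0, 0])
    psi = np.arctan2(R[2, 1], R[2, 2])
    return FickAngles(
        float(np.rad2deg(theta)), float(np.rad2deg(phi)), float(np.rad2deg(psi))
    )


def compose(R_second: np.ndarray, R_first: np.ndarray) -> np.ndarray:
    """Composite rotation: ``R_first`` applied first, then ``R_second``.

    This is the matrix product ``R_second @ R_first``, matching the
    head-then-eye composition ``G = H · E`` of gaze orientation.
    """
    return np.asarray(R_second, dtype=float) @ np.asarray(R_first, dtype=float)


def invert(R: np.ndarray) -> np.ndarray:
    return np.asarray(R, dtype=float).T.copy()


def orthonormalize(R: np.ndarray) -> np.ndarray:
    """Project onto the nearest rotation matrix (special orthogonal group).

    SVD projection ``U Vᵀ`` with the determinant sign corrected; used to
    remove accumulated floating-point drift.
    """
    R = np.asarray(R, dtype=float)
    U, _, Vt = np.linalg.svd(R)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


def listing_torsion_deg(E: np.ndarray) -> float:
    """Forward-axis rotation-vector component of an eye-in-head orientation,
    in degrees; zero exactly when the rotation axis lies in Listing's plane."""
    return float(np.rad2deg(rotvec_of(E)[0]))


def fick_torsion_deg(H: np.ndarray) -> float:
    """Fick ``psi`` of a head orientation, in degrees."""
    return fick_angles_of(H).psi
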