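"""Static kinematic planner for 3-D head-free gaze shifts.

Given an initial eye-in-head orientation ``E_i``, an initial head-in-space
orientation ``H_i``, a visual target, and three coordination parameters,
the planner solves for a coordinated three-stage movement:

1. **Saccade** ``Re``: the eye rotates in the head while the head is still.
2. **Eye-carrying head rotation** ``Rh``: the head rotates carrying the eye
   with it (eye-in-head unchanged); this stage foveates the target.
3. **Gaze-stabilized head rotation** ``Rw`` with compensatory VOR ``Rv``:
   the head completes its rotation while the vestibulo-ocular reflex
   counter-rotates the eye so gaze orientation is unchanged.

Desired orientations compose as ``E_d = Rv·Re·E_i``, ``H_d = Rw·Rh·H_i``,
``G_d = H_d·E_d``.  The solution enforces two behavioral constraints at the
final fixation: the eye-in-head orientation lies in Listing's plane (zero
rotation-vector torsion), and the head orientation has zero Fick torsion.

The coordination parameters are:

``alpha``, ``beta``
    Fractions of the horizontal / vertical gaze displacement taken up by
    the head: desired angular head position interpolates between the
    initial head direction and the desired gaze direction componentwise.
``delta``
    Phase split of the single fixed-axis head rotation ``Rt = Rw·Rh``:
    phase 1 (gaze-contributing) has magnitude ``delta·τ`` and phase 2
    (VOR-cancelled) the remainder, both about the same axis.

The solution order is: desired gaze direction → desired head angles →
Fick-constrained ``H_d`` → ``Rt = H_d·H_i⁻¹`` split by ``delta`` →
desired eye direction ``e_d = H_d⁻¹·g_d`` → Listing-constrained ``E_d`` →
total eye rotation ``Ra = E_d·E_i⁻¹`` → predicted VOR
``Rv = H_i⁻¹·Rh⁻¹·Rw⁻¹·Rh·H_i`` (from gaze stability during stage 3) →
saccade ``Re = Rv⁻¹·Ra``.  Because ``E_d``, ``H_d`` depend only on
``(alpha, beta)`` and the target, the endpoint of the movement is
independent of ``delta``; only the saccade/VOR split changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from . import rotation as rot
from .frames import (
    AngularPosition2D,
    REFERENCE_DIRECTION,
    ScreenTarget,
    angles_from_dir,
    desired_gaze_from_retinal_error,
    dir_from_angles,
    gaze_from_screen_target,
    OutOfHemisphereError,
)

__all__ = [
    "EyeHeadState",
    "PlannerParams",
    "RetinalErrorTarget",
    "GazePlan",
    "desired_head_angles",
    "fick_orientation_from_dir",
    "listing_orientation_from_dir",
    "split_rotation",
    "vor_rotation",
    "plan_gaze_shift",
    "displacement_commands",
    "UnreachableTargetError",
]


class UnreachableTargetError(ValueError):
    """Target requires an eye or head direction outside the front hemisphere."""


@dataclass(frozen=True)
class EyeHeadState:
    """Paired eye-in-head and head-in-space orientations."""

    E: np.ndarray
    H: np.ndarray

    def __post_init__(self) -> None:
        rot.check_rotation(self.E)
        rot.check_rotation(self.H)

    @property
    def G(self) -> np.ndarray:
        """Gaze (eye-in-space) orientation, recomputed as ``H · E``."""
        return self.H @ self.E

    @property
    def gaze_direction(self) -> np.ndarray:
        return self.G @ REFERENCE_DIRECTION

    @staticmethod
    def reference() -> "EyeHeadState":
        return EyeHeadState(np.eye(3), np.eye(3))


@dataclass(frozen=True)
class PlannerParams:
    """Coordination parameters and screen distance.

    ``alpha``/``beta``/``delta`` live in the closed interval [0, 1]; the
    interior is the physiological regime and the endpoints are accepted as
    well-defined limits (0: head-fixed saccade; 1: head points at the
    target / no VOR phase).
    """

    alpha: float = 0.5
    beta: float = 0.5
    delta: float = 0.5
    t: float = 100.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "delta"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")
        if self.t <= 0:
            raise ValueError(f"t must be positive; got {self.t}")


@dataclass(frozen=True)
class RetinalErrorTarget:
    """Target given as a retinal-error direction in initial eye coordinates."""

    g_RE: np.ndarray


TargetSpec = Union[ScreenTarget, AngularPosition2D, RetinalErrorTarget]


@dataclass(frozen=True)
class GazePlan:
    """Solved stage rotations, desired orientations, and displacement views.

    ``Rt = Rw·Rh`` is the single fixed-axis head rotation; ``Ra = Rv·Re``
    the total eye-in-head rotation.  ``dE``/``dH`` are rotation-vector
    displacement commands (radians): ``dE = rotvec(Re·E_i) − rotvec(E_i)``
    targets the post-saccadic eye orientation, ``dH = rotvec(H_d) −
    rotvec(H_i)`` the final head orientation.
    """

    Re: np.ndarray
    Rh: np.ndarray
    Rw: np.ndarray
    Rv: np.ndarray
    Rt: np.ndarray
    Ra: np.ndarray
    E_d: np.ndarray
    H_d: np.ndarray
    G_d: np.ndarray
    g_d: np.ndarray
    dE: np.ndarray
    dH: np.ndarray
    params: PlannerParams = field(default=PlannerParams())

    def to_dict(self) -> dict:
        """JSON-shaped record: matrices row-major, angles deg, schema tagged."""

        def mat(M: np.ndarray) -> list:
            return [[float(x) for x in row] for row in M]

        return {
            "schema": "gazekin.plan/1",
            "params": {
                "alpha": self.params.alpha,
                "beta": self.params.beta,
                "delta": self.params.delta,
                "t_cm": self.params.t,
            },
            "rotations": {
                k: mat(getattr(self, k)) for k in ("Re", "Rh", "Rw", "Rv", "Rt", "Ra")
            },
            "desired": {k: mat(getattr(self, k)) for k in ("E_d", "H_d", "G_d")},
            "g_d": [float(x) for x in self.g_d],
            "displacements_rad": {
                "dE": [float(x) for x in self.dE],
                "dH": [float(x) for x in self.dH],
            },
        }


def desired_head_angles(
    b_i: AngularPosition2D,
    c_d: AngularPosition2D,
    alpha: float,
    beta: float,
) -> AngularPosition2D:
    """Componentwise interpolation between initial head angles and desired
    gaze angles: head azimuth moves by fraction ``alpha`` of the azimuth
    gap, head elevation by fraction ``beta`` of the elevation gap."""
    return AngularPosition2D(
        b_i.gamma + alpha * (c_d.gamma - b_i.gamma),
        b_i.eta + beta * (c_d.eta - b_i.eta),
    )


def fick_orientation_from_dir(h_d: np.ndarray) -> np.ndarray:
    """Unique zero-Fick-torsion orientation pointing the head along ``h_d``.

    Fick angles follow from the direction alone: ``theta = atan2(h_y, h_x)``
    (vertical-axis rotation), ``phi = asin(−h_z)`` (interim horizontal
    axis), ``psi = 0``.
    """
    h = np.asarray(h_d, dtype=float)
    if abs(abs(h[2]) - 1.0) < 1e-12:
        raise rot.GimbalLockError("head direction at the vertical pole")
    theta = np.arctan2(h[1], h[0])
    phi = np.arcsin(np.clip(-h[2], -1.0, 1.0))
    return rot.fick_matrix(
        rot.FickAngles(float(np.rad2deg(theta)), float(np.rad2deg(phi)), 0.0)
    )


def listing_orientation_from_dir(e_d: np.ndarray) -> np.ndarray:
    """Unique Listing's-plane orientation pointing the eye along ``e_d``.

    The rotation axis is confined to the plane orthogonal to the primary
    (forward) direction: magnitude ``τ = acos(e_x)``, axis
    ``[0, −e_z, e_y] / sin τ``.  Undefined for ``e_d`` antiparallel to the
    primary direction.
    """
    e = np.asarray(e_d, dtype=float)
    # sin tau = hypot(e_y, e_z) is well-conditioned where acos(e_x) is not
    s = np.hypot(e[1], e[2])
    if s < 1e-12:
        if e[0] < 0:
            raise UnreachableTargetError(
                "eye direction 180 deg from primary position: "
                "Listing orientation undefined"
            )
        return np.eye(3)
    u = np.array([0.0, -e[2] / s, e[1] / s])
    tau = np.arctan2(s, e[0])
    return rot.rot_about_axis(u, float(np.rad2deg(tau)))


def split_rotation(Rt: np.ndarray, delta: float) -> tuple[np.ndarray, np.ndarray]:
    """Split ``Rt`` into coaxial parts ``(Rh, Rw)`` with ``Rw·Rh = Rt``:
    ``Rh`` has magnitude ``delta·τ`` and ``Rw`` the remaining
    ``(1 − delta)·τ`` about the shared axis."""
    aa = rot.axis_angle_of(Rt)
    if aa.angle_deg < 1e-12:
        return np.eye(3), np.eye(3)
    Rh = rot.rot_about_axis(aa.axis, delta * aa.angle_deg)
    Rw = rot.rot_about_axis(aa.axis, (1.0 - delta) * aa.angle_deg)
    return Rh, Rw


def vor_rotation(H_i: np.ndarray, Rh: np.ndarray, Rw: np.ndarray) -> np.ndarray:
    """Ideal VOR eye rotation predicted from the stage-3 head rotation.

    Solves the gaze-stability condition — gaze orientation after stage 3
    equals gaze orientation after stage 2 — giving
    ``Rv = H_i⁻¹·Rh⁻¹·Rw⁻¹·Rh·H_i``: the stage-3 head rotation, inverted
    and expressed in the post-stage-2 eye-carrying frame.
    """
    return H_i.T @ Rh.T @ Rw.T @ Rh @ H_i


def _resolve_desired_gaze(
    state_i: EyeHeadState, target: TargetSpec, params: PlannerParams
) -> np.ndarray:
    if isinstance(target, ScreenTarget):
        return gaze_from_screen_target(target)
    if isinstance(target, AngularPosition2D):
        return dir_from_angles(target)
    if isinstance(target, RetinalErrorTarget):
        return desired_gaze_from_retinal_error(state_i.G, target.g_RE)
    raise TypeError(f"unsupported target specification: {type(target).__name__}")


def plan_gaze_shift(
    state_i: EyeHeadState, target: TargetSpec, params: PlannerParams = PlannerParams()
) -> GazePlan:
    """Solve the full static model for one gaze shift.

    Postconditions (all exact up to floating point): the desired gaze
    orientation foveates the target (``G_d·[1,0,0] = g_d``); ``E_d`` has
    zero Listing torsion; ``H_d`` has zero Fick torsion; the stage
    compositions ``Rt = Rw·Rh``, ``Ra = Rv·Re``, ``E_d = Rv·Re·E_i``,
    ``H_d = Rw·Rh·H_i`` hold.  Raises :class:`UnreachableTargetError` when
    the desired gaze or intermediate head/eye direction leaves the front
    hemisphere.
    """
    E_i, H_i = state_i.E, state_i.H
    g_d = _resolve_desired_gaze(state_i, target, params)

    try:
        c_d = angles_from_dir(g_d)
        b_i = angles_from_dir(H_i @ REFERENCE_DIRECTION)
    except OutOfHemisphereError as exc:
        raise UnreachableTargetError(str(exc)) from exc

    b_d = desired_head_angles(b_i, c_d, params.alpha, params.beta)
    h_d = dir_from_angles(b_d)
    H_d = fick_orientation_from_dir(h_d)

    Rt = H_d @ H_i.T
    Rh, Rw = split_rotation(Rt, params.delta)

    e_d = H_d.T @ g_d
    if e_d[0] <= 0:
        raise UnreachableTargetError(
            "required eye-in-head direction leaves the front hemisphere"
        )
    E_d = listing_orientation_from_dir(e_d)

    Ra = E_d @ E_i.T
    Rv = vor_rotation(H_i, Rh, Rw)
    Re = Rv.T @ Ra

    G_d = H_d @ E_d
    dE = rot.rotvec_of(Re @ E_i) - rot.rotvec_of(E_i)
    dH = rot.rotvec_of(H_d) - rot.rotvec_of(H_i)

    return GazePlan(
        Re=Re, Rh=Rh, Rw=Rw, Rv=Rv, Rt=Rt, Ra=Ra,
        E_d=E_d, H_d=H_d, G_d=G_d, g_d=g_d, dE=dE, dH=dH,
        params=params,
    )


def displacement_commands(
    plan: GazePlan, state_i: EyeHeadState
) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-vector displacement commands (radians).

    ``dE`` subtracts the initial eye rotation vector from the post-saccadic
    one; ``dH`` subtracts the initial head rotation vector from the final
    one.  Both are zero vectors exactly when no movement is required.
    """
    dE = rot.rotvec_of(plan.Re @ state_i.E) - rot.rotvec_of(state_i.E)
    dH = rot.rotvec_of(plan.H_d) - rot.rotvec_of(state_i.H)
    return dE, dH
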