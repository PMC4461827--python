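"""Simulation suites: orientation-range scans, twist quantification, and
accuracy / trajectory drivers.

These drivers exercise the planner and trajectory simulator over structured
target sets and tabulate the outcomes:

* ``run_range_scan`` plans gaze shifts from one initial state to a grid of
  angular targets and records the final eye-in-head, head-in-space, and
  eye-in-space (gaze) orientations, decomposed into rotation-vector
  components and Fick angles.  Plotted as torsion versus horizontal
  rotation, a Fick-constrained range forms the characteristic "bow-tie":
  torsion is (in quaternion units, exactly) ``−sin(θ/2)·sin(φ/2)`` for
  vertical-axis angle θ and horizontal-axis angle φ.
* ``twist_score`` summarizes such a range by the least-squares coefficient
  ``k`` in ``torsion ≈ k · horizontal · vertical`` over rotation-vector
  components (radians).  Under this package's sign conventions a Fick-like
  range gives ``k < 0`` and a Helmholtz-like range ``k > 0``; a pure
  Listing range gives ``k = 0``.
* ``run_fig4`` simulates rightward gaze shifts in two input modes — fixed
  screen targets (−40 cm to +40 cm at several altitudes) and a fixed
  rightward retinal error from several initial fixations — and tracks the
  gaze point on the screen and the target image on the retina; accurate
  planning drives the retinal image of the target onto the fovea.
* ``run_trajectory_suite`` simulates shifts between two vertical columns of
  screen targets and exposes the transient torsion excursions: the eye
  leaves Listing's plane during the saccade and is brought back by the
  VOR; the head leaves the static Fick surface mid-flight on its single
  fixed-axis rotation between two Fick-compliant endpoints.

All drivers are pure functions of their arguments — rerunning reproduces
identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import rotation as rot
from .frames import (
    AngularPosition2D,
    REFERENCE_DIRECTION,
    ScreenTarget,
    angles_from_dir,
    dir_from_angles,
    retinal_error_vector,
    retinal_eccentricity_deg,
)
from .planner import (
    EyeHeadState,
    GazePlan,
    PlannerParams,
    RetinalErrorTarget,
    listing_orientation_from_dir,
    plan_gaze_shift,
)
from .trajectory import TimingProfile, TrajectorySample, simulate, trajectory_frame

__all__ = [
    "target_grid",
    "run_range_scan",
    "twist_score",
    "run_fig4",
    "Fig4Shift",
    "run_trajectory_suite",
]

#: Default vertical altitudes (cm) for the horizontal-shift accuracy suite.
DEFAULT_ALTITUDES_CM = (-40.0, -20.0, 0.0, 20.0, 40.0)


def target_grid(
    h_range: tuple[float, float] = (-40.0, 40.0),
    v_range: tuple[float, float] = (-40.0, 40.0),
    n_per_axis: int = 41,
) -> list[AngularPosition2D]:
    """Uniform ``n × n`` grid of angular targets (deg), row-major with the
    horizontal coordinate varying fastest."""
    gammas = np.linspace(h_range[0], h_range[1], n_per_axis)
    etas = np.linspace(v_range[0], v_range[1], n_per_axis)
    return [AngularPosition2D(float(g), float(e)) for e in etas for g in gammas]


def _orientation_columns(prefix: str, R: np.ndarray) -> dict[str, float]:
    rv = np.rad2deg(rot.rotvec_of(R))
    fa = rot.fick_angles_of(R)
    return {
        f"{prefix}_rx_deg": rv[0],
        f"{prefix}_ry_deg": rv[1],
        f"{prefix}_rz_deg": rv[2],
        f"{prefix}_fick_theta_deg": fa.theta,
        f"{prefix}_fick_phi_deg": fa.phi,
        f"{prefix}_fick_psi_deg": fa.psi,
    }


def run_range_scan(
    params: PlannerParams,
    grid: list[AngularPosition2D] | None = None,
    state_i: EyeHeadState | None = None,
) -> pd.DataFrame:
    """Final-orientation table over a target grid.

    One row per target with columns ``target_gamma_deg``, ``target_eta_deg``
    and, for each of ``eye`` (eye-in-head), ``head``, ``gaze``
    (eye-in-space): rotation-vector components ``*_r{x,y,z}_deg`` and Fick
    angles ``*_fick_{theta,phi,psi}_deg``.
    """
    if grid is None:
        grid = target_grid()
    if state_i is None:
        state_i = EyeHeadState.reference()
    rows = []
    for tgt in grid:
        plan = plan_gaze_shift(state_i, tgt, params)
        row: dict[str, float] = {
            "target_gamma_deg": tgt.gamma,
            "target_eta_deg": tgt.eta,
        }
        row.update(_orientation_columns("eye", plan.E_d))
        row.update(_orientation_columns("head", plan.H_d))
        row.update(_orientation_columns("gaze", plan.G_d))
        rows.append(row)
    return pd.DataFrame(rows)


def twist_score(table: pd.DataFrame, which: str = "gaze") -> float:
    """Least-squares twist coefficient of an orientation range.

    Fits ``torsion ≈ k · (horizontal · vertical)`` on rotation-vector
    components converted to radians: torsion ``r_x``, vertical ``r_y``,
    horizontal ``r_z``.  ``k < 0`` marks a Fick-like twist, ``k > 0`` a
    Helmholtz-like twist; an all-zero torsion range (Listing) returns 0.
    """
    if which not in ("eye", "head", "gaze"):
        raise ValueError("which must be one of 'eye', 'head', 'gaze'")
    rx = np.deg2rad(table[f"{which}_rx_deg"].to_numpy())
    ry = np.deg2rad(table[f"{which}_ry_deg"].to_numpy())
    rz = np.deg2rad(table[f"{which}_rz_deg"].to_numpy())
    x = rz * ry
    denom = float(np.dot(x, x))
    if denom < 1e-30 or float(np.max(np.abs(rx))) < 1e-15:
        return 0.0
    return float(np.dot(rx, x) / denom)


@dataclass(frozen=True)
class Fig4Shift:
    """One simulated shift of the accuracy suite."""

    altitude_cm: float
    state_i: EyeHeadState
    plan: GazePlan
    trajectory: pd.DataFrame
    screen_path: pd.DataFrame  # gaze intersection on the screen (cm)
    retinal_path: pd.DataFrame  # target image in retinal coordinates (deg)
    final_retinal_eccentricity_deg: float


def _initial_state_fixating(point: ScreenTarget) -> EyeHeadState:
    """Reference head, eye fixating ``point`` via a Listing-plane orientation."""
    from .frames import gaze_from_screen_target

    e_dir = gaze_from_screen_target(point)
    return EyeHeadState(listing_orientation_from_dir(e_dir), np.eye(3))


def _retinal_path(samples: list[TrajectorySample], g_d: np.ndarray) -> pd.DataFrame:
    rows = []
    for s in samples:
        g_re = retinal_error_vector(s.state.G, g_d)
        ang = angles_from_dir(g_re)  # azimuth/elevation of the target image
        rows.append(
            {
                "time_ms": s.time_ms,
                "re_gamma_deg": ang.gamma,
                "re_eta_deg": ang.eta,
                "eccentricity_deg": retinal_eccentricity_deg(g_re),
            }
        )
    return pd.DataFrame(rows)


def run_fig4(
    condition: str = "screen",
    params: PlannerParams = PlannerParams(),
    altitudes_cm: tuple[float, ...] = DEFAULT_ALTITUDES_CM,
    timing: TimingProfile = TimingProfile(),
    n_samples: int = 120,
    retinal_error_deg: float = 60.0,
    horizontal_extent_cm: float = 40.0,
) -> list[Fig4Shift]:
    """Accuracy suite: rightward gaze shifts from several vertical altitudes.

    ``condition='screen'``: shift from the screen point
    ``(−horizontal_extent_cm, altitude)`` to ``(+horizontal_extent_cm,
    altitude)`` at the configured screen distance.  ``condition='retinal'``:
    from the same initial fixations, a fixed retinal error of
    ``retinal_error_deg`` toward positive azimuth.  Each shift is planned,
    simulated, and tracked on the screen and on the retina; the retinal
    path of an accurate shift terminates at the fovea.
    """
    if condition not in ("screen", "retinal"):
        raise ValueError("condition must be 'screen' or 'retinal'")
    shifts = []
    for alt in altitudes_cm:
        start = ScreenTarget(-horizontal_extent_cm, alt, params.t)
        state_i = _initial_state_fixating(start)
        if condition == "screen":
            target = ScreenTarget(horizontal_extent_cm, alt, params.t)
        else:
            g_re = dir_from_angles(AngularPosition2D(retinal_error_deg, 0.0))
            target = RetinalErrorTarget(g_re)
        plan = plan_gaze_shift(state_i, target, params)
        samples = simulate(plan, state_i, timing, n_samples)
        traj = trajectory_frame(samples, params.t)
        screen_path = traj[["time_ms", "screen_a_cm", "screen_b_cm"]].copy()
        retinal = _retinal_path(samples, plan.g_d)
        final_ecc = float(retinal["eccentricity_deg"].iloc[-1])
        shifts.append(
            Fig4Shift(alt, state_i, plan, traj, screen_path, retinal, final_ecc)
        )
    return shifts


def run_trajectory_suite(
    column_targets_cm: tuple[float, ...] = (-40.0, 0.0, 40.0),
    params: PlannerParams = PlannerParams(),
    timing: TimingProfile = TimingProfile(),
    n_samples: int = 120,
    from_x_cm: float = -40.0,
    to_x_cm: float = 40.0,
) -> list[dict]:
    """All shifts from one vertical column of screen targets to another.

    For each (start altitude, end altitude) pair, plans and simulates the
    shift and returns the trajectory table plus its peak and endpoint
    torsion metrics: eye Listing torsion (rotation-vector x, deg) and head
    Fick psi (deg).
    """
    results = []
    for b0 in column_targets_cm:
        start = ScreenTarget(from_x_cm, b0, params.t)
        state_i = _initial_state_fixating(start)
        for b1 in column_targets_cm:
            target = ScreenTarget(to_x_cm, b1, params.t)
            plan = plan_gaze_shift(state_i, target, params)
            samples = simulate(plan, state_i, timing, n_samples)
            traj = trajectory_frame(samples, params.t)
            eye_tors = traj["eye_rx_deg"].to_numpy()
            head_psi = traj["head_fick_psi_deg"].to_numpy()
            results.append(
                {
                    "from_cm": (from_x_cm, b0),
                    "to_cm": (to_x_cm, b1),
                    "plan": plan,
                    "trajectory": traj,
                    "eye_torsion_start_deg": float(eye_tors[0]),
                    "eye_torsion_end_deg": float(eye_tors[-1]),
                    "eye_torsion_peak_deg": float(np.max(np.abs(eye_tors))),
                    "head_psi_start_deg": float(head_psi[0]),
                    "head_psi_end_deg": float(head_psi[-1]),
                    "head_psi_peak_deg": float(np.max(np.abs(head_psi))),
                }
            )
    return results
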