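"""Temporal discretization of a solved gaze plan into orientation time courses.

The static planner fixes *what* rotations happen; this module fixes *when*.
All rotations except the VOR keep a constant axis and grow their magnitude
with a monotone scalar growth function of normalized time.  The head
executes its single fixed-axis rotation ``Rt`` continuously: phase 1 covers
the gaze-contributing fraction ``delta`` of the magnitude, phase 2 the
remainder.  During phase 2 the eye is driven by an ideal online VOR: at
each sample the eye-in-head orientation is re-solved as
``E(t) = H(t)⁻¹ · G_stage2`` so the full 3-D gaze orientation (not just its
direction) is constant — equivalent to integrating the ideal angular-velocity
command but numerically exact.

Timing is deliberately loose: saccade and head onsets are independent (they
may overlap), but the saccade must end no later than phase 2 begins, so the
ideal-VOR substitution is unambiguous.  The endpoints of the movement are a
function of the plan alone — any valid timing profile reaches the same
final state, because succession of the planned rotations does not dictate
the timing of their implementation.

Velocity realism is out of scope: the growth functions shape nothing the
model's questions depend on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import rotation as rot
from .frames import REFERENCE_DIRECTION, screen_target_from_gaze
from .planner import EyeHeadState, GazePlan

__all__ = [
    "TimingProfile",
    "TrajectorySample",
    "growth",
    "simulate",
    "trajectory_frame",
    "GROWTH_KINDS",
]


def _smoothstep(s: float) -> float:
    return s * s * (3.0 - 2.0 * s)


GROWTH_KINDS: dict[str, Callable[[float], float]] = {
    "linear": lambda s: s,
    "smoothstep": _smoothstep,
}


def growth(s: float, kind: str = "smoothstep") -> float:
    """Scalar growth function: monotone, ``growth(0)=0``, ``growth(1)=1``."""
    if kind not in GROWTH_KINDS:
        raise ValueError(
            f"unknown growth kind {kind!r}; available: {sorted(GROWTH_KINDS)}"
        )
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"normalized time must lie in [0, 1]; got {s}")
    return float(GROWTH_KINDS[kind](float(s)))


@dataclass(frozen=True)
class TimingProfile:
    """Stage timing in milliseconds.

    Defaults (saccade 0–100 ms; head phase 1 0–150 ms, phase 2 150–400 ms)
    are configurable conventions, not behavioral claims.  The saccade must
    end no later than head phase 2 begins.
    """

    saccade_onset: float = 0.0
    saccade_duration: float = 100.0
    head_onset: float = 0.0
    head_phase1_duration: float = 150.0
    head_phase2_duration: float = 250.0
    growth_kind: str = "smoothstep"

    def __post_init__(self) -> None:
        for name in ("saccade_duration", "head_phase1_duration", "head_phase2_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.saccade_end > self.phase2_start:
            raise ValueError(
                "saccade must end before the VOR stage: require "
                "saccade_onset + saccade_duration <= head_onset + head_phase1_duration"
            )
        if self.growth_kind not in GROWTH_KINDS:
            raise ValueError(f"unknown growth kind {self.growth_kind!r}")

    @property
    def saccade_end(self) -> float:
        return self.saccade_onset + self.saccade_duration

    @property
    def phase2_start(self) -> float:
        return self.head_onset + self.head_phase1_duration

    @property
    def head_end(self) -> float:
        return self.phase2_start + self.head_phase2_duration

    @property
    def span(self) -> float:
        return max(self.saccade_end, self.head_end)


@dataclass(frozen=True)
class TrajectorySample:
    time_ms: float
    state: EyeHeadState
    stage_label: str  # pre | saccade | head_phase1 | head_phase2_vor | done


def _fraction(t: float, onset: float, duration: float, kind: str) -> float:
    if t <= onset:
        return 0.0
    if t >= onset + duration:
        return 1.0
    return growth((t - onset) / duration, kind)


def simulate(
    plan: GazePlan,
    state_i: EyeHeadState,
    timing: TimingProfile = TimingProfile(),
    n: int = 200,
) -> list[TrajectorySample]:
    """Sample the movement at ``n`` uniformly spaced times over its span.

    Eye-in-head: fixed-axis partial saccade ``rot(u_Re, g(s)·τ_Re)·E_i``
    until the saccade ends, held until phase 2, then ideal online VOR.
    Head: fixed-axis partial rotation along ``u_Rt``, phase 1 covering
    ``delta·τ_Rt`` and phase 2 the rest.  The last sample reproduces the
    plan's desired condition exactly.
    """
    if n < 2:
        raise ValueError("need at least two samples")
    E_i, H_i = state_i.E, state_i.H
    delta = plan.params.delta
    kind = timing.growth_kind

    aa_re = rot.axis_angle_of(plan.Re)
    aa_rt = rot.axis_angle_of(plan.Rt)
    tau_rt = aa_rt.angle_deg

    # gaze orientation after stage 2 (foveating), held fixed during the VOR
    G_stage2 = plan.Rh @ H_i @ plan.Re @ E_i

    times = np.linspace(0.0, timing.span, n)
    samples: list[TrajectorySample] = []
    for t in times:
        # head magnitude fraction: phase 1 then phase 2, one axis throughout
        f1 = _fraction(t, timing.head_onset, timing.head_phase1_duration, kind)
        f2 = _fraction(t, timing.phase2_start, timing.head_phase2_duration, kind)
        head_frac = delta * f1 + (1.0 - delta) * f2
        H = (
            rot.rot_about_axis(aa_rt.axis, head_frac * tau_rt) @ H_i
            if tau_rt > 0
            else H_i.copy()
        )

        in_vor = t >= timing.phase2_start and tau_rt > 0 and delta < 1.0
        if in_vor:
            E = H.T @ G_stage2
        else:
            fs = _fraction(t, timing.saccade_onset, timing.saccade_duration, kind)
            E = (
                rot.rot_about_axis(aa_re.axis, fs * aa_re.angle_deg) @ E_i
                if aa_re.angle_deg > 0
                else E_i.copy()
            )

        if t >= timing.span:
            label = "done"
        elif in_vor:
            label = "head_phase2_vor"
        elif timing.saccade_onset <= t < timing.saccade_end:
            label = "saccade"
        elif timing.head_onset <= t < timing.phase2_start:
            label = "head_phase1"
        else:
            label = "pre"

        samples.append(TrajectorySample(float(t), EyeHeadState(E, H), label))
    return samples


def trajectory_frame(
    samples: Sequence[TrajectorySample] | Iterable[TrajectorySample],
    screen_distance_cm: float = 100.0,
) -> pd.DataFrame:
    """Tidy table of a trajectory.

    Per sample: time, stage label; eye/head/gaze rotation-vector components
    (deg) and Fick angles (deg); gaze screen intersection (cm, central
    projection).  Conventions: x forward, y left, z up; torsion is the
    x rotation-vector component / Fick psi.
    """
    rows = []
    for s in samples:
        E, H = s.state.E, s.state.H
        G = s.state.G
        row: dict[str, float | str] = {"time_ms": s.time_ms, "stage": s.stage_label}
        for name, R in (("eye", E), ("head", H), ("gaze", G)):
            rv = np.rad2deg(rot.rotvec_of(R))
            row[f"{name}_rx_deg"] = rv[0]
            row[f"{name}_ry_deg"] = rv[1]
            row[f"{name}_rz_deg"] = rv[2]
            fa = rot.fick_angles_of(R)
            row[f"{name}_fick_theta_deg"] = fa.theta
            row[f"{name}_fick_phi_deg"] = fa.phi
            row[f"{name}_fick_psi_deg"] = fa.psi
        g_dir = G @ REFERENCE_DIRECTION
        tgt = screen_target_from_gaze(g_dir, screen_distance_cm)
        row["screen_a_cm"] = tgt.a
        row["screen_b_cm"] = tgt.b
        rows.append(row)
    return pd.DataFrame(rows)
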