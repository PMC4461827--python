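"""Seeded generators of random valid initial states and targets.

Generated eye-in-head orientations are exactly Listing-compliant (rotation
axis in the y–z plane) and generated head orientations are exactly
Fick-compliant (zero Fick torsion); the planner does not require compliant
inputs, but compliant fixtures match the behavioral regime the model
describes.  Eccentricities are bounded below 45 deg so that planned
intermediate directions stay comfortably inside the front hemisphere.
"""

from __future__ import annotations

import numpy as np

from . import rotation as rot
from .frames import AngularPosition2D
from .planner import EyeHeadState, fick_orientation_from_dir

__all__ = [
    "random_listing_eye",
    "random_fick_head",
    "random_states",
    "random_targets",
]


def random_listing_eye(
    rng: np.random.Generator, max_eccentricity_deg: float = 45.0
) -> np.ndarray:
    """Rotation about a random axis in Listing's plane (the y–z plane) by a
    random magnitude below ``max_eccentricity_deg``."""
    phase = rng.uniform(0.0, 2.0 * np.pi)
    axis = np.array([0.0, np.cos(phase), np.sin(phase)])
    tau = rng.uniform(0.0, max_eccentricity_deg)
    return rot.rot_about_axis(axis, tau)


def random_fick_head(
    rng: np.random.Generator, max_eccentricity_deg: float = 45.0
) -> np.ndarray:
    """Zero-Fick-torsion orientation whose forward direction has a random
    eccentricity below ``max_eccentricity_deg``."""
    ecc = np.deg2rad(rng.uniform(0.0, max_eccentricity_deg))
    phase = rng.uniform(0.0, 2.0 * np.pi)
    # forward direction tilted by `ecc` toward a random transverse direction
    d = np.array(
        [np.cos(ecc), np.sin(ecc) * np.cos(phase), np.sin(ecc) * np.sin(phase)]
    )
    if abs(abs(d[2]) - 1.0) < 1e-9:  # avoid the gimbal pole
        d = np.array([np.cos(ecc), np.sin(ecc), 0.0])
    return fick_orientation_from_dir(d)


def random_states(
    seed: int, n: int, max_eccentricity_deg: float = 45.0
) -> list[EyeHeadState]:
    """``n`` reproducible Listing/Fick-compliant initial states."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    return [
        EyeHeadState(
            random_listing_eye(rng, max_eccentricity_deg),
            random_fick_head(rng, max_eccentricity_deg),
        )
        for _ in range(n)
    ]


def random_targets(
    seed: int, n: int, max_angle_deg: float = 40.0
) -> list[AngularPosition2D]:
    """``n`` reproducible angular targets uniform in the square
    ``(−max_angle_deg, max_angle_deg)²``."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    return [
        AngularPosition2D(
            float(rng.uniform(-max_angle_deg, max_angle_deg)),
            float(rng.uniform(-max_angle_deg, max_angle_deg)),
        )
        for _ in range(n)
    ]
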