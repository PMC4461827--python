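"""Run configuration: a YAML-editable record resolving to planner inputs.

Units are fixed: angles in degrees, distances in cm, times in ms.  A
resolved configuration plus a seed determines every output byte — drivers
are pure functions, so identical configs reproduce identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .fixtures import random_fick_head, random_listing_eye
from .frames import AngularPosition2D, ScreenTarget, dir_from_angles
from .planner import (
    EyeHeadState,
    PlannerParams,
    RetinalErrorTarget,
    TargetSpec,
    listing_orientation_from_dir,
)
from .rotation import FickAngles, fick_matrix
from .trajectory import TimingProfile

__all__ = ["RunConfig", "ConfigError", "load_config", "resolve_state", "resolve_target"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


@dataclass(frozen=True)
class InitialStateSpec:
    """Initial eye/head orientations.

    ``kind='reference'``: identity orientations.  ``kind='angles'``: the eye
    takes the Listing-plane orientation pointing at ``(eye_gamma, eye_eta)``
    and the head the zero-torsion Fick orientation ``(head_theta,
    head_phi)``.  ``kind='random'``: seeded Listing/Fick-compliant draw.
    """

    kind: str = "reference"
    eye_gamma: float = 0.0
    eye_eta: float = 0.0
    head_theta: float = 0.0
    head_phi: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class TargetSpecConfig:
    """Target: ``kind`` is 'screen' (cm offsets), 'angles' (deg), or
    'retinal_error' (deg direction of the target image on the retina)."""

    kind: str = "screen"
    a: float = 0.0
    b: float = 0.0
    gamma: float = 0.0
    eta: float = 0.0


@dataclass(frozen=True)
class RunConfig:
    params: PlannerParams = field(default_factory=PlannerParams)
    timing: TimingProfile = field(default_factory=TimingProfile)
    initial_state: InitialStateSpec = field(default_factory=InitialStateSpec)
    target: TargetSpecConfig = field(default_factory=TargetSpecConfig)
    n_samples: int = 200
    seed: int = 0
    out_dir: str = "gazekin_out"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _build(cls: type, section: str, data: dict[str, Any]):
    if not isinstance(data, dict):
        raise ConfigError(f"section '{section}' must be a mapping")
    valid = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
    for key in data:
        if key not in valid:
            raise ConfigError(f"unknown field '{section}.{key}'")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        # planner/timing dataclasses name the bad field in their message
        raise ConfigError(f"invalid value in section '{section}': {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top-level configuration must be a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    for key in raw:
        if key not in known:
            raise ConfigError(f"unknown field '{key}'")
    kwargs: dict[str, Any] = {}
    if "params" in raw:
        kwargs["params"] = _build(PlannerParams, "params", raw["params"])
    if "timing" in raw:
        kwargs["timing"] = _build(TimingProfile, "timing", raw["timing"])
    if "initial_state" in raw:
        kwargs["initial_state"] = _build(
            InitialStateSpec, "initial_state", raw["initial_state"]
        )
    if "target" in raw:
        kwargs["target"] = _build(TargetSpecConfig, "target", raw["target"])
    for key in ("n_samples", "seed", "out_dir"):
        if key in raw:
            kwargs[key] = raw[key]
    cfg = RunConfig(**kwargs)
    if cfg.n_samples < 2:
        raise ConfigError("n_samples must be at least 2")
    return cfg


def resolve_state(spec: InitialStateSpec) -> EyeHeadState:
    if spec.kind == "reference":
        return EyeHeadState.reference()
    if spec.kind == "angles":
        E = listing_orientation_from_dir(
            dir_from_angles(AngularPosition2D(spec.eye_gamma, spec.eye_eta))
        )
        H = fick_matrix(FickAngles(spec.head_theta, spec.head_phi, 0.0))
        return EyeHeadState(E, H)
    if spec.kind == "random":
        rng = np.random.default_rng(spec.seed)
        return EyeHeadState(random_listing_eye(rng), random_fick_head(rng))
    raise ConfigError(f"initial_state.kind must be 'reference', 'angles' or 'random'; got {spec.kind!r}")


def resolve_target(spec: TargetSpecConfig, params: PlannerParams) -> TargetSpec:
    if spec.kind == "screen":
        return ScreenTarget(spec.a, spec.b, params.t)
    if spec.kind == "angles":
        return AngularPosition2D(spec.gamma, spec.eta)
    if spec.kind == "retinal_error":
        return RetinalErrorTarget(
            dir_from_angles(AngularPosition2D(spec.gamma, spec.eta))
        )
    raise ConfigError(
        f"target.kind must be 'screen', 'angles' or 'retinal_error'; got {spec.kind!r}"
    )
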