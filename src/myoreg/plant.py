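"""Virtual hand-wrist prosthesis plant.

A first-order kinematic stand-in for the physical hardware: a gripper
(terminal device) whose aperture integrates a signed mm/s command between
travel limits, and a wrist rotator whose angle integrates a signed deg/s
command without limits.  Speed envelopes follow the commercial hardware the
controllers target: proportional gripper speed 8-200 mm/s and wrist
rotation up to 28 rpm (168 deg/s).  No motor dynamics or backlash are
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["PlantSpec", "PlantState", "plant_step", "simulate_plant"]


@dataclass
class PlantSpec:
    hand_speed_min_mm_s: float = 8.0
    hand_speed_max_mm_s: float = 200.0
    aperture_min_mm: float = 0.0
    aperture_max_mm: float = 100.0  # Greifer travel not published; configurable
    wrist_speed_max_rpm: float = 28.0
    wrist_speed_min_deg_s: float = 0.0
    loop_hz: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 < self.hand_speed_min_mm_s < self.hand_speed_max_mm_s:
            raise ValueError("need 0 < hand min speed < hand max speed")
        if self.aperture_min_mm >= self.aperture_max_mm:
            raise ValueError("aperture_min_mm must be below aperture_max_mm")
        if self.wrist_speed_max_rpm <= 0:
            raise ValueError("wrist_speed_max_rpm must be positive")
        if self.loop_hz <= 0:
            raise ValueError("loop_hz must be positive")

    @property
    def wrist_speed_max_deg_s(self) -> float:
        return self.wrist_speed_max_rpm * 360.0 / 60.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PlantSpec":
        return cls(**d)


@dataclass
class PlantState:
    aperture_mm: float = 100.0
    wrist_angle_deg: float = 0.0  # + = pronation; unbounded
    t_s: float = 0.0


def plant_step(state: PlantState, cmd, spec: PlantSpec) -> PlantState:
    """Euler-integrate one loop period; aperture is clamped at its travel
    limits (command absorbed at the stop), the wrist is unclamped."""
    dt = 1.0 / spec.loop_hz
    ap = state.aperture_mm + cmd.hand_mm_s * dt
    ap = float(np.clip(ap, spec.aperture_min_mm, spec.aperture_max_mm))
    return PlantState(
        aperture_mm=ap,
        wrist_angle_deg=state.wrist_angle_deg + cmd.wrist_deg_s * dt,
        t_s=state.t_s + dt,
    )


def simulate_plant(commands, spec: PlantSpec, initial: PlantState | None = None) -> list[PlantState]:
    """Integrate a sequence of velocity commands; returns the state after
    every step (initial state not included)."""
    state = initial or PlantState(aperture_mm=spec.aperture_max_mm)
    out = []
    for cmd in commands:
        state = plant_step(state, cmd, spec)
        out.append(state)
    return out
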