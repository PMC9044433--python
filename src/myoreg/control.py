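"""Per-frame controllers: thresholding, co-activation gating, velocity
mapping, and the sequential two-site state machine.

Regression control (DirCon/MapCon) composes, at 100 Hz:

    EMGσ frame -> force estimate -> resting thresholds -> fixed-ratio
    co-activation gate -> linear velocity map

The resting thresholds (default 10 %MVC per direction, four in total)
suppress noise and unintentional low-level activity.  The fixed-ratio
co-activation gate suppresses the smaller-magnitude DoF whenever the
(hand, wrist) force vector lies within an angle alpha (default 25 deg) of
the dominant axis; vectors further from the axes drive both DoFs
simultaneously.  Force then maps linearly to velocity with 50 %MVC
corresponding to maximum speed.

Sequential control (SeqCon) scales two channels so 30 %MVC corresponds to
each channel's calibration contraction; the algebraic difference
(extensor - flexor) drives one DoF at a time, and a sustained
co-contraction (both channels above their co-contraction thresholds for a
set window, 30-100 ms) toggles between hand and wrist.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .calibration import CalibrationSchedule, EmgForceResults
from .plant import PlantSpec
from .signal import SigmaSeries

__all__ = [
    "ControllerConfig",
    "SeqConSpec",
    "SeqConState",
    "VelocityCommand",
    "apply_rest_threshold",
    "coactivation_gate",
    "force_to_velocity",
    "regression_controller_step",
    "seqcon_calibrate",
    "seqcon_step",
]

DT_MS = 10.0  # 100 Hz control loop


@dataclass
class VelocityCommand:
    hand_mm_s: float = 0.0
    wrist_deg_s: float = 0.0


@dataclass
class ControllerConfig:
    """Runtime configuration for the regression controllers.

    ``rest_thresholds`` is keyed by direction (open, close, pro, sup —
    MapCon reuses the same four keys for its mapped axes); each is a %MVC
    dead zone.  ``gate_alpha_deg`` is the co-activation angle,
    ``vel_sat_pct`` the effort at which velocity saturates.
    """

    rest_thresholds: dict[str, float] = field(
        default_factory=lambda: {"open": 10.0, "close": 10.0, "pro": 10.0, "sup": 10.0}
    )
    gate_alpha_deg: float = 25.0
    vel_sat_pct: float = 50.0
    invert_hand: bool = False
    invert_wrist: bool = False

    def __post_init__(self) -> None:
        missing = {"open", "close", "pro", "sup"} - set(self.rest_thresholds)
        if missing:
            raise ValueError(f"rest_thresholds missing direction(s): {sorted(missing)}")
        if any(v < 0 for v in self.rest_thresholds.values()):
            raise ValueError("rest thresholds must be nonnegative")
        if not 0.0 <= self.gate_alpha_deg < 45.0:
            raise ValueError("gate_alpha_deg must lie in [0, 45)")
        if not 0.0 < self.vel_sat_pct <= 100.0:
            raise ValueError("vel_sat_pct must lie in (0, 100]")
        if any(v >= self.vel_sat_pct for v in self.rest_thresholds.values()):
            raise ValueError("rest thresholds must be below vel_sat_pct")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ControllerConfig":
        return cls(**d)


def _dir_threshold(cfg: ControllerConfig, dof: int, value: float) -> float:
    if dof == 0:
        return cfg.rest_thresholds["open" if value >= 0 else "close"]
    return cfg.rest_thresholds["pro" if value >= 0 else "sup"]


def apply_rest_threshold(f: np.ndarray, cfg: ControllerConfig) -> np.ndarray:
    """Hard per-direction dead zone: a component whose magnitude is below
    its direction's threshold becomes exactly zero."""
    out = np.array(f, dtype=np.float64)
    for dof in (0, 1):
        if abs(out[dof]) < _dir_threshold(cfg, dof, out[dof]):
            out[dof] = 0.0
    return out


def coactivation_gate(f: np.ndarray, alpha_deg: float) -> np.ndarray:
    """Fixed-ratio co-activation gate in the (hand, wrist) force plane.

    With a = atan2(min(|hand|,|wrist|), max(|hand|,|wrist|)): when the
    vector lies within ``alpha_deg`` of the dominant axis (a < alpha), only
    the larger-magnitude DoF is actuated; otherwise both pass.  Equal
    magnitudes (a = 45 deg) always pass.
    """
    out = np.array(f, dtype=np.float64)
    lo, hi = sorted(np.abs(out))
    a = np.degrees(np.arctan2(lo, hi))
    if a < alpha_deg:
        out[int(np.argmin(np.abs(out)))] = 0.0
    return out


def _map_axis(
    value: float, thr: float, sat: float, v_min: float, v_max: float
) -> float:
    """Linear |force| -> speed map: threshold -> minimum actuation speed,
    saturation effort -> maximum speed, clamped beyond; zero stays zero."""
    if value == 0.0:
        return 0.0
    m = min(max(abs(value), thr), sat)
    speed = v_min + (m - thr) / (sat - thr) * (v_max - v_min)
    return float(np.sign(value)) * speed


def force_to_velocity(
    f: np.ndarray, cfg: ControllerConfig, plant: PlantSpec
) -> VelocityCommand:
    """Map a thresholded/gated force estimate to a velocity command, with
    ``vel_sat_pct`` (default 50 %MVC) corresponding to maximum speed."""
    hand = _map_axis(
        f[0],
        _dir_threshold(cfg, 0, f[0]),
        cfg.vel_sat_pct,
        plant.hand_speed_min_mm_s,
        plant.hand_speed_max_mm_s,
    )
    wrist = _map_axis(
        f[1],
        _dir_threshold(cfg, 1, f[1]),
        cfg.vel_sat_pct,
        plant.wrist_speed_min_deg_s,
        plant.wrist_speed_max_deg_s,
    )
    if cfg.invert_hand:
        hand = -hand
    if cfg.invert_wrist:
        wrist = -wrist
    return VelocityCommand(hand_mm_s=hand, wrist_deg_s=wrist)


def regression_controller_step(
    sigma_frame: np.ndarray,
    channel_names: list[str],
    results: EmgForceResults,
    cfg: ControllerConfig,
    plant: PlantSpec,
) -> VelocityCommand:
    """One 100 Hz loop iteration of DirCon/MapCon.

    The runtime path is identical for both strategies — the mapped
    semantics live entirely in the calibration labels and the inversion
    flags.
    """
    f = results.predict_frame(sigma_frame, channel_names)
    f = apply_rest_threshold(f, cfg)
    f = coactivation_gate(f, cfg.gate_alpha_deg)
    return force_to_velocity(f, cfg, plant)


# -- sequential two-site control ------------------------------------------


@dataclass
class SeqConSpec:
    """Two-site sequential controller parameters.

    Gains scale raw EMGσ to %MVC so that each channel's dedicated
    calibration contraction reads 30 %MVC.  A co-contraction (both scaled
    channels above their co-contraction thresholds for ``window_ms``)
    toggles the active DoF; ``refractory_ms`` then suppresses output.
    """

    ext_channel: int
    flx_channel: int
    gain_ext: float
    gain_flx: float
    rest_thr_ext: float = 10.0
    rest_thr_flx: float = 10.0
    cocon_thr_ext: float = 45.0
    cocon_thr_flx: float = 45.0
    window_ms: float = 50.0
    refractory_ms: float = 300.0
    vel_sat_pct: float = 50.0
    suppress_during_detection: bool = False
    initial_dof: str = "hand"

    def __post_init__(self) -> None:
        if self.ext_channel == self.flx_channel:
            raise ValueError("ext and flx channels must differ")
        if not 30.0 <= self.window_ms <= 100.0:
            raise ValueError("window_ms must lie in [30, 100]")
        for name in ("rest_thr_ext", "rest_thr_flx", "cocon_thr_ext", "cocon_thr_flx"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SeqConSpec":
        return cls(**d)


@dataclass
class SeqConState:
    active_dof: str = "hand"
    cocon_elapsed_ms: float = 0.0
    refractory_remaining_ms: float = 0.0
    armed: bool = True


def seqcon_calibrate(
    sigma: SigmaSeries,
    schedule: CalibrationSchedule,
    ext_channel: int,
    flx_channel: int,
    trim_s: float = 1.0,
) -> SeqConSpec:
    """Set channel gains from the calibration session.

    gain_c = 30 / (mean EMGσ of channel c over its dedicated trimmed
    segment) — the extension segment for the extensor channel, flexion for
    the flexor — so each channel's calibration contraction corresponds to
    30 %MVC.  Co-contraction thresholds default midway between 30 %MVC and
    the session-wide peak scaled value; all thresholds remain editable.
    """
    if ext_channel == flx_channel:
        raise ValueError("ext and flx channels must differ")
    fs = sigma.fs_hz

    def seg_mean(label: str, channel: int) -> float:
        for lab, start_s, dur_s in schedule.segments:
            if lab == label:
                i0 = int(round(start_s * fs + trim_s * fs))
                i1 = int(round((start_s + dur_s) * fs - trim_s * fs))
                return float(sigma.sigma[i0:i1, channel].mean())
        raise ValueError(f"schedule has no {label!r} segment (use the mapped-strategy schedule)")

    gains = {}
    for label, ch, key in (("Ext", ext_channel, "ext"), ("Flx", flx_channel, "flx")):
        m = seg_mean(label, ch)
        if m <= 0.0:
            raise ValueError(f"channel {ch} has zero mean EMGσ over its {label} segment")
        gains[key] = 30.0 / m

    peak_ext = gains["ext"] * float(sigma.sigma[:, ext_channel].max())
    peak_flx = gains["flx"] * float(sigma.sigma[:, flx_channel].max())
    return SeqConSpec(
        ext_channel=ext_channel,
        flx_channel=flx_channel,
        gain_ext=gains["ext"],
        gain_flx=gains["flx"],
        cocon_thr_ext=(30.0 + max(peak_ext, 30.0)) / 2.0,
        cocon_thr_flx=(30.0 + max(peak_flx, 30.0)) / 2.0,
    )


def seqcon_step(
    sigma_frame: np.ndarray,
    spec: SeqConSpec,
    state: SeqConState,
    plant: PlantSpec,
) -> tuple[VelocityCommand, SeqConState]:
    """One 100 Hz iteration of sequential control.

    The co-contraction timer accumulates while BOTH scaled channels exceed
    their co-contraction thresholds; on reaching ``window_ms`` the active
    DoF toggles exactly once, the refractory starts (output forced to
    zero), and detection re-arms only after the co-contraction condition
    breaks — so one sustained co-contraction yields one toggle.  Otherwise
    the net force (extensor - flexor, after per-channel dead zones) drives
    the active DoF; the inactive DoF is always zero.
    """
    s_ext = spec.gain_ext * float(sigma_frame[spec.ext_channel])
    s_flx = spec.gain_flx * float(sigma_frame[spec.flx_channel])
    if s_ext < spec.rest_thr_ext:
        s_ext = 0.0
    if s_flx < spec.rest_thr_flx:
        s_flx = 0.0
    both_above = s_ext > spec.cocon_thr_ext and s_flx > spec.cocon_thr_flx

    window_frames = max(1, int(round(spec.window_ms / DT_MS)))
    suppressed = False
    if not both_above:
        state.armed = True  # a break in the co-contraction re-arms detection
    if state.refractory_remaining_ms > 0.0:
        state.refractory_remaining_ms = max(0.0, state.refractory_remaining_ms - DT_MS)
        state.cocon_elapsed_ms = 0.0
        suppressed = True
    elif both_above and state.armed:
        state.cocon_elapsed_ms += DT_MS
        if spec.suppress_during_detection:
            suppressed = True
        if state.cocon_elapsed_ms >= window_frames * DT_MS:
            state.active_dof = "wrist" if state.active_dof == "hand" else "hand"
            state.cocon_elapsed_ms = 0.0
            state.refractory_remaining_ms = spec.refractory_ms
            state.armed = False
            suppressed = True  # the toggle consumes this frame
    else:
        state.cocon_elapsed_ms = 0.0

    if suppressed:
        return VelocityCommand(), state

    net = s_ext - s_flx
    thr = spec.rest_thr_ext if net >= 0 else spec.rest_thr_flx
    if state.active_dof == "hand":
        v = _map_axis(net, thr, spec.vel_sat_pct, plant.hand_speed_min_mm_s, plant.hand_speed_max_mm_s)
        return VelocityCommand(hand_mm_s=v), state
    v = _map_axis(net, thr, spec.vel_sat_pct, plant.wrist_speed_min_deg_s, plant.wrist_speed_max_deg_s)
    return VelocityCommand(wrist_deg_s=v), state
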