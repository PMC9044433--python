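"""Seeded surface-EMG simulator.

Generates calibration and free-run sessions with known ground-truth
efforts, standing in for subjects and electrodes.  The model is the
standard amplitude-modulation view of surface EMG: each channel is a
band-limited, unit-variance Gaussian carrier (20-450 Hz) multiplied by a
slowly varying amplitude envelope

    amp_c(t) = noise_floor_c + sum_d gains[c, d] * effort_d(t)

plus optional additive 60 Hz power-line interference.  Efforts are
nonnegative per-direction drives in %MVC along four primitive directions
(hand +, hand -, wrist +, wrist -; e.g. open/close/pro/sup for direct
control).  Electrode gains are circumferentially tuned: each direction
peaks on a distinct contiguous arc of channels with smooth cosine falloff,
mimicking equally spaced electrodes around the forearm.

Everything is deterministic given the session seed: per-channel carriers
and per-direction effort jitter draw from independently spawned
sub-streams of one seed sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .calibration import CalibrationSchedule, _DIRECTION_AXIS
from .signal import RawEmg

__all__ = [
    "DIRECTION_COLUMNS",
    "MixingModel",
    "EffortTrajectory",
    "SessionSpec",
    "make_mixing",
    "effort_from_schedule",
    "synthesize_emg",
    "ground_truth_force",
    "make_session",
]

# Effort/gain column order: (DoF, sign) -> column.  Column 0/1 drive the
# hand axis (+/-), column 2/3 the wrist axis (+/-).
DIRECTION_COLUMNS = ("hand+", "hand-", "wrist+", "wrist-")
_AXIS_TO_COLUMN = {(0, +1.0): 0, (0, -1.0): 1, (1, +1.0): 2, (1, -1.0): 3}


def _direction_column(label_part: str) -> int:
    axis, sign = _DIRECTION_AXIS[label_part]
    return _AXIS_TO_COLUMN[(axis, sign)]


@dataclass
class MixingModel:
    """Nonnegative channel x direction amplitude gains plus noise floor."""

    gains: np.ndarray  # (n_channels, 4), amplitude units per %MVC
    noise_floor: np.ndarray  # (n_channels,), baseline amplitude
    interference_amp: float = 0.0  # additive 60 Hz amplitude

    def __post_init__(self) -> None:
        self.gains = np.asarray(self.gains, dtype=np.float64)
        self.noise_floor = np.asarray(self.noise_floor, dtype=np.float64)
        if self.gains.ndim != 2 or self.gains.shape[1] != 4:
            raise ValueError("gains must be (n_channels, 4)")
        if np.any(self.gains < 0):
            raise ValueError("gains must be nonnegative")
        for d in range(4):
            col = self.gains[:, d]
            if not np.any(col > 2.0 * self.noise_floor):
                raise ValueError(
                    f"direction column {d} unobservable: no gain exceeds 2x its channel's noise floor"
                )

    @property
    def n_channels(self) -> int:
        return self.gains.shape[0]


def make_mixing(
    n_channels: int,
    seed: int,
    noise_channels: tuple[int, ...] = (),
    interference_amp: float = 0.02,
) -> MixingModel:
    """Circumferentially tuned electrode gains.

    Each of the four directions peaks on a distinct contiguous arc of the
    informative channels with smooth cosine falloff; the arc offset is
    drawn from the seed, so different seeds place the peaks on different
    channels.  ``noise_channels`` get zero gain everywhere (pure noise
    floor), emulating electrodes over electrically silent tissue.
    """
    if n_channels < 4:
        raise ValueError("need at least 4 channels to observe 4 directions")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA1]))
    informative = [c for c in range(n_channels) if c not in set(noise_channels)]
    m = len(informative)
    if m < 4:
        raise ValueError("need at least 4 informative channels")
    gains = np.zeros((n_channels, 4))
    offset = rng.uniform(0.0, m)
    width = m / 4.0  # half-width of each arc, in channel units
    for d in range(4):
        centre = (offset + d * m / 4.0) % m
        for pos, ch in enumerate(informative):
            dist = min(abs(pos - centre), m - abs(pos - centre))
            if dist < width:
                gains[ch, d] = np.cos(0.5 * np.pi * dist / width)
    # Arc position fixes each electrode's *relative* direction preference;
    # overall sensitivity (electrode coupling, tissue) is drawn per channel,
    # so every informative electrode sits over active muscle.
    sens = rng.uniform(0.02, 0.03, size=n_channels)
    for ch in informative:
        gains[ch] *= sens[ch] / gains[ch].max()
    noise_floor = rng.uniform(0.003, 0.008, size=n_channels)
    return MixingModel(gains=gains, noise_floor=noise_floor, interference_amp=interference_amp)


@dataclass
class SessionSpec:
    """Session-generation parameters (all randomness stems from ``seed``)."""

    seed: int = 0
    fs_hz: float = 2000.0
    loop_hz: float = 100.0
    ramp_s: float = 0.5
    effort_jitter_rel: float = 0.1  # slow multiplicative effort wander
    channel_wander_rel: float = 0.08  # slow per-channel amplitude wander
    carrier_band_hz: tuple[float, float] = (20.0, 450.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.effort_jitter_rel < 1.0:
            raise ValueError("effort_jitter_rel must lie in [0, 1)")
        if not 0.0 <= self.channel_wander_rel < 1.0:
            raise ValueError("channel_wander_rel must lie in [0, 1)")
        lo, hi = self.carrier_band_hz
        if not 0.0 < lo < hi < self.fs_hz / 2.0:
            raise ValueError("carrier band must lie inside (0, fs/2)")


@dataclass
class EffortTrajectory:
    """Nonnegative per-direction efforts (%MVC) at the loop rate."""

    efforts: np.ndarray  # (frames, 4), columns per DIRECTION_COLUMNS
    fs_hz: float = 100.0

    def __post_init__(self) -> None:
        self.efforts = np.asarray(self.efforts, dtype=np.float64)
        if self.efforts.ndim != 2 or self.efforts.shape[1] != 4:
            raise ValueError("efforts must be (frames, 4)")
        if np.any(self.efforts < 0):
            raise ValueError("efforts must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.efforts.shape[0]


def effort_from_schedule(
    schedule: CalibrationSchedule, effort_pct: float, spec: SessionSpec
) -> EffortTrajectory:
    """Realise a calibration schedule as effort time courses.

    Each active direction ramps to ``effort_pct`` over ``ramp_s`` (raised
    cosine), holds with slow multiplicative jitter, and ramps off; Rest is
    all-zero.  The jitter emulates a subject's inability to hold a fixed
    force level without feedback.
    """
    fs = spec.loop_hz
    n = int(round(schedule.total_s * fs))
    eff = np.zeros((n, 4))
    for label, start_s, dur_s in schedule.segments:
        if label == "Rest":
            continue
        i0, i1 = int(round(start_s * fs)), int(round((start_s + dur_s) * fs))
        seg_n = i1 - i0
        ramp_n = min(int(round(spec.ramp_s * fs)), seg_n // 2)
        prof = np.ones(seg_n)
        if ramp_n > 0:
            r = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
            prof[:ramp_n] = r
            prof[seg_n - ramp_n :] = r[::-1]
        for part in label.split("+"):
            eff[i0:i1, _direction_column(part)] = effort_pct * prof
    if spec.effort_jitter_rel > 0.0:
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xB2]))
        # slow wander: white noise through a one-pole lowpass (~0.5 Hz),
        # rescaled so its std matches the requested relative jitter
        a = float(np.exp(-2.0 * np.pi * 0.5 / fs))
        for d in range(4):
            w = sps.lfilter([1.0 - a], [1.0, -a], rng.standard_normal(n))
            w = w / w.std() * spec.effort_jitter_rel
            eff[:, d] *= np.maximum(0.0, 1.0 + w)
    return EffortTrajectory(efforts=eff, fs_hz=fs)


def synthesize_emg(
    traj: EffortTrajectory, mixing: MixingModel, spec: SessionSpec
) -> RawEmg:
    """Amplitude-modulate per-channel carriers by the effort envelope.

    The 100 Hz envelope is held (zero-order) up to the raw rate; each
    channel's carrier is an independent seeded band-limited Gaussian
    normalised to unit variance.  On top of the shared effort drive, every
    channel's amplitude wanders slowly and independently
    (``channel_wander_rel``): individual muscles do not track the
    four-direction effort exactly (force sharing, electrode coupling
    drift), so per-channel activity carries variability of its own.
    """
    factor = int(round(spec.fs_hz / traj.fs_hz))
    amp = mixing.noise_floor[None, :] + traj.efforts @ mixing.gains.T
    if spec.channel_wander_rel > 0.0:
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xD4]))
        a = float(np.exp(-2.0 * np.pi * 0.5 / traj.fs_hz))  # ~0.5 Hz wander
        for c in range(mixing.n_channels):
            w = sps.lfilter([1.0 - a], [1.0, -a], rng.standard_normal(amp.shape[0]))
            w = w / w.std() * spec.channel_wander_rel
            amp[:, c] *= np.maximum(0.0, 1.0 + w)
    amp = np.repeat(amp, factor, axis=0)
    n = amp.shape[0]
    sos = sps.butter(4, spec.carrier_band_hz, btype="bandpass", fs=spec.fs_hz, output="sos")
    ss = np.random.SeedSequence([int(spec.seed), 0xC3])
    children = ss.spawn(mixing.n_channels)
    out = np.empty((n, mixing.n_channels))
    for c in range(mixing.n_channels):
        rng = np.random.default_rng(children[c])
        carrier = sps.sosfilt(sos, rng.standard_normal(n))
        carrier /= carrier.std()
        out[:, c] = amp[:, c] * carrier
    if mixing.interference_amp != 0.0:
        t = np.arange(n) / spec.fs_hz
        out += mixing.interference_amp * np.sin(2.0 * np.pi * 60.0 * t)[:, None]
    names = [f"ch{c:02d}" for c in range(mixing.n_channels)]
    return RawEmg(samples=out, fs_hz=spec.fs_hz, channel_names=names)


def ground_truth_force(traj: EffortTrajectory) -> np.ndarray:
    """Signed (hand, wrist) truth per frame: (hand+ - hand-, wrist+ - wrist-)."""
    e = traj.efforts
    return np.column_stack([e[:, 0] - e[:, 1], e[:, 2] - e[:, 3]])


def make_session(
    schedule: CalibrationSchedule,
    n_channels: int = 16,
    seed: int = 0,
    effort_pct: float = 30.0,
    noise_channels: tuple[int, ...] = (),
    spec: SessionSpec | None = None,
    mixing: MixingModel | None = None,
) -> tuple[RawEmg, EffortTrajectory, MixingModel]:
    """Convenience: mixing + efforts + raw EMG for one schedule."""
    spec = spec if spec is not None else SessionSpec(seed=seed)
    if mixing is None:
        mixing = make_mixing(n_channels, seed=seed, noise_channels=noise_channels)
    traj = effort_from_schedule(schedule, effort_pct, spec)
    raw = synthesize_emg(traj, mixing, spec)
    return raw, traj, mixing
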