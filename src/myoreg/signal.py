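"""Causal EMG amplitude estimation (EMGσ).

Raw multichannel surface EMG sampled at 2000 Hz is turned into a 100 Hz
per-channel amplitude series through a five-stage causal cascade:

1. power-line notch (second-order IIR, 60 Hz, 1 Hz -3 dB bandwidth),
2. motion-artifact highpass (Butterworth, 15 Hz, order 5),
3. full-wave rectification,
4. Chebyshev type-I lowpass (16 Hz, order 9, 0.05 dB ripple),
5. decimation to 100 Hz followed by a critically damped smoother
   (two identical one-pole sections, cascade -3 dB at 1 Hz).

The result is EMGσ -- a running estimate of the EMG standard deviation,
a.k.a. processed EMG -- in the raw signal's amplitude units.  All stages
are causal with all-zero initial state (cold start); downstream calibration
trims the first second of every segment, which absorbs startup transients.

Batch and streaming paths share the same recursions, so feeding a recording
sample-by-sample through :func:`process_step` is bit-identical to
:func:`process_batch` on the whole array.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import signal as sps

__all__ = [
    "RawEmg",
    "SigmaSeries",
    "FilterSpec",
    "FilterBank",
    "StreamState",
    "design_filter_bank",
    "process_batch",
    "process_step",
]


@dataclass
class RawEmg:
    """Multichannel raw EMG (rows = samples, cols = channels)."""

    samples: np.ndarray
    fs_hz: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D array (samples x channels)")
        if self.samples.shape[1] < 2:
            raise ValueError("raw EMG needs at least 2 channels")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.channel_names) != self.samples.shape[1]:
            raise ValueError("channel_names length must match channel count")
        if not np.all(np.isfinite(self.samples)):
            idx = np.argwhere(~np.isfinite(self.samples))[0]
            raise ValueError(
                f"non-finite sample at row {idx[0]}, channel "
                f"{self.channel_names[idx[1]]} (index {idx[1]})"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class SigmaSeries:
    """Per-channel EMGσ at the control loop rate (100 Hz by default)."""

    sigma: np.ndarray
    fs_hz: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.sigma.ndim != 2:
            raise ValueError("sigma must be 2-D (frames x channels)")
        if np.any(self.sigma < 0):
            raise ValueError("EMGσ must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.sigma.shape[0]

    @property
    def n_channels(self) -> int:
        return self.sigma.shape[1]


@dataclass
class FilterSpec:
    """Parameters of the amplitude-estimation cascade.

    Defaults realise the standard 2000 Hz -> 100 Hz pipeline; every cutoff
    must stay below the Nyquist rate of the stage it applies to.
    """

    notch_hz: float = 60.0
    notch_bw_hz: float = 1.0
    hp_fc_hz: float = 15.0
    hp_order: int = 5
    lp_fc_hz: float = 16.0
    lp_order: int = 9
    lp_ripple_db: float = 0.05
    decim_factor: int = 20
    smooth_fc_hz: float = 1.0
    smooth_order: int = 2

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterSpec":
        return cls(**d)


def _one_pole_sos(fc_hz: float, fs_hz: float, order: int) -> np.ndarray:
    """Cascade of ``order`` identical one-pole lowpass sections whose overall
    -3 dB frequency is exactly ``fc_hz`` (critically damped: multiple real pole).

    Each section is H(z) = (1-a) / (1 - a z^-1); the pole ``a`` is solved in
    closed form so the cascade magnitude is 1/sqrt(2) at ``fc_hz``.
    """
    w = 2.0 * np.pi * fc_hz / fs_hz
    g = 2.0 ** (-1.0 / order)  # per-section |H|^2 target at fc
    c = np.cos(w)
    p = 1.0 - g * c
    q = 1.0 - g
    a = (p - np.sqrt(p * p - q * q)) / q
    sec = np.array([1.0 - a, 0.0, 0.0, 1.0, -a, 0.0])
    return np.tile(sec, (order, 1))


@dataclass
class FilterBank:
    """Designed cascade stages in second-order-section form."""

    sos_notch: np.ndarray
    sos_hp: np.ndarray
    sos_lp: np.ndarray
    sos_smooth: np.ndarray
    decim_factor: int
    fs_in_hz: float
    fs_out_hz: float
    spec: FilterSpec

    def stages(self) -> dict[str, tuple[np.ndarray, float]]:
        """Stage name -> (sos, design rate), for response inspection."""
        return {
            "notch": (self.sos_notch, self.fs_in_hz),
            "highpass": (self.sos_hp, self.fs_in_hz),
            "lowpass": (self.sos_lp, self.fs_in_hz),
            "smoother": (self.sos_smooth, self.fs_out_hz),
        }


def design_filter_bank(spec: FilterSpec, fs_hz: float) -> FilterBank:
    """Design all cascade stages for a given raw sampling rate.

    Raises a :class:`ValueError` naming the offending stage if any cutoff
    reaches the Nyquist rate of the signal it filters, and checks that every
    recursive stage is stable (poles strictly inside the unit circle).
    """
    nyq = fs_hz / 2.0
    if spec.notch_hz >= nyq:
        raise ValueError(f"notch stage: centre {spec.notch_hz} Hz >= Nyquist {nyq} Hz")
    if spec.hp_fc_hz >= nyq:
        raise ValueError(f"highpass stage: cutoff {spec.hp_fc_hz} Hz >= Nyquist {nyq} Hz")
    if spec.lp_fc_hz >= nyq:
        raise ValueError(f"lowpass stage: cutoff {spec.lp_fc_hz} Hz >= Nyquist {nyq} Hz")
    if spec.decim_factor < 1 or fs_hz % spec.decim_factor != 0:
        raise ValueError(
            f"decimation stage: factor {spec.decim_factor} does not divide fs {fs_hz} Hz"
        )
    fs_out = fs_hz / spec.decim_factor
    if spec.smooth_fc_hz >= fs_out / 2.0:
        raise ValueError(
            f"smoother stage: cutoff {spec.smooth_fc_hz} Hz >= output Nyquist {fs_out / 2.0} Hz"
        )

    # -3 dB notch bandwidth convention: Q = f0 / bw
    b, a = sps.iirnotch(spec.notch_hz, spec.notch_hz / spec.notch_bw_hz, fs=fs_hz)
    sos_notch = sps.tf2sos(b, a)
    sos_hp = sps.butter(spec.hp_order, spec.hp_fc_hz, btype="highpass", fs=fs_hz, output="sos")
    sos_lp = sps.cheby1(
        spec.lp_order, spec.lp_ripple_db, spec.lp_fc_hz, btype="lowpass", fs=fs_hz, output="sos"
    )
    sos_smooth = _one_pole_sos(spec.smooth_fc_hz, fs_out, spec.smooth_order)

    bank = FilterBank(
        sos_notch=sos_notch,
        sos_hp=sos_hp,
        sos_lp=sos_lp,
        sos_smooth=sos_smooth,
        decim_factor=spec.decim_factor,
        fs_in_hz=fs_hz,
        fs_out_hz=fs_out,
        spec=spec,
    )
    for name, (sos, _) in bank.stages().items():
        # poles straight from the section denominators (sos2zpk would warn
        # about the Chebyshev sections' tiny numerators)
        poles = np.concatenate([np.roots(section[3:]) for section in sos])
        if np.any(np.abs(poles) >= 1.0):
            raise ValueError(f"{name} stage: unstable (pole on/outside unit circle)")
    return bank


def process_batch(raw: RawEmg, bank: FilterBank) -> SigmaSeries:
    """Run the full cascade over a recording, one channel at a time.

    Output length is ``floor(n_samples / decim_factor)``: a frame is emitted
    after every ``decim_factor`` raw samples, matching the streaming path
    exactly. Momentary undershoot from Chebyshev ringing is clamped to zero,
    since EMGσ is an amplitude estimate.
    """
    if raw.fs_hz != bank.fs_in_hz:
        raise ValueError(
            f"raw sampled at {raw.fs_hz} Hz but bank designed for {bank.fs_in_hz} Hz"
        )
    x = raw.samples
    y = sps.sosfilt(bank.sos_notch, x, axis=0)
    y = sps.sosfilt(bank.sos_hp, y, axis=0)
    y = np.abs(y)
    y = sps.sosfilt(bank.sos_lp, y, axis=0)
    y = y[bank.decim_factor - 1 :: bank.decim_factor]
    y = sps.sosfilt(bank.sos_smooth, y, axis=0)
    return SigmaSeries(np.maximum(y, 0.0), bank.fs_out_hz, list(raw.channel_names))


@dataclass
class StreamState:
    """Carried filter state for sample-by-sample processing."""

    bank: FilterBank
    n_channels: int
    zi_notch: np.ndarray = field(init=False)
    zi_hp: np.ndarray = field(init=False)
    zi_lp: np.ndarray = field(init=False)
    zi_smooth: np.ndarray = field(init=False)
    phase: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        c = self.n_channels

        def zeros(sos: np.ndarray) -> np.ndarray:
            return np.zeros((sos.shape[0], 2, c))

        self.zi_notch = zeros(self.bank.sos_notch)
        self.zi_hp = zeros(self.bank.sos_hp)
        self.zi_lp = zeros(self.bank.sos_lp)
        self.zi_smooth = zeros(self.bank.sos_smooth)


def process_step(
    frame: np.ndarray, state: StreamState
) -> tuple[Optional[np.ndarray], StreamState]:
    """Push one raw multichannel sample; emit an EMGσ frame every
    ``decim_factor`` samples, bit-identical to the batch path."""
    frame = np.asarray(frame, dtype=np.float64).reshape(1, -1)
    if frame.shape[1] != state.n_channels:
        raise ValueError(
            f"frame has {frame.shape[1]} channels, state expects {state.n_channels}"
        )
    bank = state.bank
    y, state.zi_notch = sps.sosfilt(bank.sos_notch, frame, axis=0, zi=state.zi_notch)
    y, state.zi_hp = sps.sosfilt(bank.sos_hp, y, axis=0, zi=state.zi_hp)
    y = np.abs(y)
    y, state.zi_lp = sps.sosfilt(bank.sos_lp, y, axis=0, zi=state.zi_lp)
    state.phase += 1
    if state.phase < bank.decim_factor:
        return None, state
    state.phase = 0
    y, state.zi_smooth = sps.sosfilt(bank.sos_smooth, y, axis=0, zi=state.zi_smooth)
    return np.maximum(y[0], 0.0), state
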