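"""Calibration of the linear EMGσ-force model.

A 90 s calibration session consists of 10 s of rest followed by eight
contiguous 10 s constant-posture contractions at a nominal 30 %MVC target
effort.  For direct control (DirCon) the sequence engages hand open-close
and wrist pronation-supination; for mapped control (MapCon) it engages
wrist extension-flexion (driving hand open-close) and radial-ulnar
deviation (driving wrist rotation).

From the processed EMGσ the design data is assembled (first/last second of
each segment trimmed, the rest segment replicated eight times to balance
the fit), and a two-output linear model

    F = X @ W,   F in signed %MVC (hand, wrist)

is fitted by the truncated-SVD pseudo-inverse: singular values are removed
when their ratio to the largest falls below a tolerance (default 0.01).
Calibration quality is the RMSE between target and estimated force, pooled
over both DoF outputs, reported per contraction type and overall.  Backward
stepwise selection greedily drops the channel whose removal yields the
lowest training RMSE until a target electrode count remains.

The surface follows the model/results idiom: :class:`EmgForceModel` holds
the design, ``fit()`` / ``select_channels()`` return
:class:`EmgForceResults` with coefficients, diagnostics, ``predict`` and
``summary``.  Thin functional wrappers (:func:`fit_pseudo_inverse`,
:func:`backward_select`, :func:`predict`, :func:`quality_rmse`) expose the
same steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .signal import SigmaSeries

__all__ = [
    "DIRCON",
    "MAPCON",
    "CalibrationSchedule",
    "FitSpec",
    "DesignData",
    "QualityReport",
    "EmgForceModel",
    "EmgForceResults",
    "build_schedule",
    "targets_for",
    "assemble_design",
    "fit_pseudo_inverse",
    "backward_select",
    "predict",
    "quality_rmse",
]

DIRCON = "dircon"
MAPCON = "mapcon"

# Per-strategy contraction sequences (Rest first, then four 1-DoF and four
# 2-DoF contractions) and the sign each primitive direction contributes:
# hand axis + = open (DirCon) / extension (MapCon); wrist axis + = pronation
# (DirCon) / radial deviation (MapCon).
_SEQUENCES: dict[str, list[str]] = {
    DIRCON: ["Rest", "Cls", "Opn", "Sup", "Pro", "Cls+Sup", "Cls+Pro", "Opn+Sup", "Opn+Pro"],
    MAPCON: ["Rest", "Flx", "Ext", "Uln", "Rad", "Flx+Uln", "Flx+Rad", "Ext+Uln", "Ext+Rad"],
}

# direction -> (DoF index, sign); DoF 0 = hand, DoF 1 = wrist
_DIRECTION_AXIS: dict[str, tuple[int, float]] = {
    "Opn": (0, +1.0), "Cls": (0, -1.0),
    "Pro": (1, +1.0), "Sup": (1, -1.0),
    "Ext": (0, +1.0), "Flx": (0, -1.0),
    "Rad": (1, +1.0), "Uln": (1, -1.0),
}

SEGMENT_S = 10.0


@dataclass
class CalibrationSchedule:
    """Ordered contraction segments: (label, start_s, duration_s)."""

    segments: list[tuple[str, float, float]]
    strategy: str

    @property
    def total_s(self) -> float:
        last = self.segments[-1]
        return last[1] + last[2]

    @property
    def labels(self) -> list[str]:
        return [s[0] for s in self.segments]


def build_schedule(strategy: str) -> CalibrationSchedule:
    """The 90 s schedule: Rest then eight 10 s contractions, in the
    strategy's fixed order."""
    if strategy not in _SEQUENCES:
        raise ValueError(f"unknown strategy {strategy!r}; expected 'dircon' or 'mapcon'")
    labels = _SEQUENCES[strategy]
    segs = [(lab, i * SEGMENT_S, SEGMENT_S) for i, lab in enumerate(labels)]
    return CalibrationSchedule(segments=segs, strategy=strategy)


def targets_for(label: str, effort_pct: float) -> np.ndarray:
    """Signed (hand, wrist) %MVC target for one contraction type.

    Active directions map to ±effort_pct; any unused DoF targets zero.
    """
    y = np.zeros(2)
    if label == "Rest":
        return y
    for part in label.split("+"):
        if part not in _DIRECTION_AXIS:
            raise ValueError(f"unknown contraction component {part!r} in {label!r}")
        axis, sign = _DIRECTION_AXIS[part]
        y[axis] = sign * effort_pct
    return y


@dataclass
class FitSpec:
    """Fit configuration.

    tol
        Singular-value truncation ratio of the pseudo-inverse.
    rest_weight
        How many times the rest segment's rows are replicated; eight
        balances one rest segment against eight active segments.
    effort_pct
        Nominal target effort per active direction, %MVC.
    trim_s
        Seconds trimmed from both ends of every segment (filter and
        movement transients).
    bias
        Include a constant-1 column to absorb the EMGσ noise floor.
    """

    tol: float = 0.01
    rest_weight: int = 8
    effort_pct: float = 30.0
    trim_s: float = 1.0
    bias: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.tol < 1.0:
            raise ValueError("tol must lie in (0, 1)")
        if self.rest_weight < 1:
            raise ValueError("rest_weight must be >= 1")
        if not 0.0 < self.effort_pct <= 100.0:
            raise ValueError("effort_pct must lie in (0, 100]")
        if 2.0 * self.trim_s >= SEGMENT_S:
            raise ValueError("2*trim_s must be smaller than the segment duration")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FitSpec":
        return cls(**d)


@dataclass
class DesignData:
    """Row-aligned regression data: X (EMGσ [+ bias]), Y (signed %MVC)."""

    X: np.ndarray
    Y: np.ndarray
    row_labels: np.ndarray  # contraction type per row
    channel_names: list[str]
    bias: bool

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


def assemble_design(
    sigma: SigmaSeries, schedule: CalibrationSchedule, spec: FitSpec
) -> DesignData:
    """Trim segment edges on the 100 Hz grid, replicate the rest block, and
    stack the design matrix with its signed force targets."""
    fs = sigma.fs_hz
    need = int(round(schedule.total_s * fs))
    if sigma.n_frames < need:
        missing = (need - sigma.n_frames) / fs
        raise ValueError(
            f"EMGσ covers only {sigma.n_frames / fs:.2f} s of the "
            f"{schedule.total_s:.0f} s schedule ({missing:.2f} s missing)"
        )
    trim = int(round(spec.trim_s * fs))
    blocks_x, blocks_y, blocks_lab = [], [], []
    for label, start_s, dur_s in schedule.segments:
        i0 = int(round(start_s * fs)) + trim
        i1 = int(round((start_s + dur_s) * fs)) - trim
        seg = sigma.sigma[i0:i1]
        y = np.tile(targets_for(label, spec.effort_pct), (seg.shape[0], 1))
        reps = spec.rest_weight if label == "Rest" else 1
        for _ in range(reps):
            blocks_x.append(seg)
            blocks_y.append(y)
            blocks_lab.append(np.full(seg.shape[0], label, dtype=object))
    X = np.vstack(blocks_x)
    if spec.bias:
        X = np.hstack([X, np.ones((X.shape[0], 1))])
    return DesignData(
        X=X,
        Y=np.vstack(blocks_y),
        row_labels=np.concatenate(blocks_lab),
        channel_names=list(sigma.channel_names),
        bias=spec.bias,
    )


@dataclass
class QualityReport:
    """Calibration-quality RMSE (in %MVC), pooled over both DoF outputs."""

    rmse_by_type: dict[str, float]
    rmse_overall: float


def _svd_solve(X: np.ndarray, Y: np.ndarray, tol: float) -> tuple[np.ndarray, int]:
    """Minimum-norm least squares via SVD with relative truncation: retain
    singular value s_i iff s_i / s_max >= tol."""
    if X.shape[0] < 2:
        raise ValueError("design must have at least 2 rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite entries in design data")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if s[0] == 0.0:
        raise ValueError("degenerate design: all singular values are zero")
    keep = s / s[0] >= tol
    n_kept = int(np.count_nonzero(keep))
    coef = Vt[keep].T @ ((U[:, keep].T @ Y) / s[keep, None])
    return coef, n_kept


class EmgForceModel:
    """Two-output linear EMGσ-force model over a calibration design.

    Parameters
    ----------
    design
        Assembled calibration data (see :func:`assemble_design`).
    strategy
        ``"dircon"`` or ``"mapcon"``; carried through to results so the
        controller knows the axis semantics.
    """

    def __init__(self, design: DesignData, strategy: str = DIRCON):
        self.design = design
        self.strategy = strategy

    @classmethod
    def from_session(
        cls,
        sigma: SigmaSeries,
        schedule: CalibrationSchedule,
        spec: FitSpec | None = None,
    ) -> "EmgForceModel":
        spec = spec or FitSpec()
        return cls(assemble_design(sigma, schedule, spec), strategy=schedule.strategy)

    # -- fitting ----------------------------------------------------------

    def fit(self, tol: float = 0.01, channels: list[int] | None = None) -> "EmgForceResults":
        """Truncated-SVD pseudo-inverse fit, optionally on a channel subset."""
        d = self.design
        if channels is None:
            channels = list(range(d.n_channels))
        cols = list(channels) + ([d.n_channels] if d.bias else [])
        coef, n_kept = _svd_solve(d.X[:, cols], d.Y, tol)
        res = EmgForceResults(
            model=self,
            coef=coef,
            channels=list(channels),
            strategy=self.strategy,
            tol_used=tol,
            n_singular_retained=n_kept,
            bias_enabled=d.bias,
        )
        res.quality = res._compute_quality()
        return res

    def select_channels(self, k: int, tol: float = 0.01) -> "EmgForceResults":
        """Backward stepwise selection down to ``k`` channels.

        Each step refits with every single remaining channel removed and
        permanently drops the one whose removal gives the lowest overall
        training RMSE; ties are broken by dropping the lowest channel index.
        The bias column is never a removal candidate.
        """
        d = self.design
        if not 1 <= k <= d.n_channels:
            raise ValueError(f"k={k} outside [1, {d.n_channels}]")
        current = list(range(d.n_channels))
        while len(current) > k:
            best_rmse, best_ch = np.inf, None
            for ch in current:
                trial = [c for c in current if c != ch]
                res = self.fit(tol=tol, channels=trial)
                r = res.quality.rmse_overall
                if r < best_rmse:  # strict: ties keep the earlier (lower) index
                    best_rmse, best_ch = r, ch
            current = [c for c in current if c != best_ch]
        return self.fit(tol=tol, channels=current)


@dataclass
class EmgForceResults:
    """Fitted EMGσ-force map with its diagnostics.

    ``coef`` has one row per selected channel (plus a final bias row when
    fitted with an intercept) and two columns: hand, wrist (signed %MVC per
    EMGσ unit).
    """

    model: EmgForceModel | None
    coef: np.ndarray
    channels: list[int]
    strategy: str
    tol_used: float
    n_singular_retained: int
    bias_enabled: bool
    channel_names: list[str] = field(default_factory=list)
    quality: QualityReport | None = None

    def __post_init__(self) -> None:
        if not self.channel_names and self.model is not None:
            self.channel_names = [
                self.model.design.channel_names[c] for c in self.channels
            ]

    # -- prediction -------------------------------------------------------

    def predict(self, sigma: SigmaSeries | np.ndarray) -> np.ndarray:
        """Estimated (hand, wrist) force in signed %MVC per frame.

        Accepts a :class:`SigmaSeries` whose channels are a superset of the
        fitted ones (matched by name) or a bare array already restricted to
        the fitted channels, in order.
        """
        if isinstance(sigma, SigmaSeries):
            missing = [c for c in self.channel_names if c not in sigma.channel_names]
            if missing:
                raise ValueError(f"sigma is missing fitted channel(s): {missing}")
            idx = [sigma.channel_names.index(c) for c in self.channel_names]
            Xc = sigma.sigma[:, idx]
        else:
            Xc = np.atleast_2d(np.asarray(sigma, dtype=np.float64))
            if Xc.shape[1] != len(self.channels):
                raise ValueError(
                    f"expected {len(self.channels)} channel columns, got {Xc.shape[1]}"
                )
        if self.bias_enabled:
            Xc = np.hstack([Xc, np.ones((Xc.shape[0], 1))])
        return Xc @ self.coef

    def predict_frame(self, sigma_frame: np.ndarray, channel_names: list[str]) -> np.ndarray:
        """Single-frame prediction for the 100 Hz control loop."""
        idx = [channel_names.index(c) for c in self.channel_names]
        x = np.asarray(sigma_frame, dtype=np.float64)[idx]
        if self.bias_enabled:
            x = np.append(x, 1.0)
        return x @ self.coef

    # -- diagnostics ------------------------------------------------------

    def _compute_quality(self) -> QualityReport:
        d = self.model.design
        cols = list(self.channels) + ([d.n_channels] if d.bias else [])
        resid = d.X[:, cols] @ self.coef - d.Y
        sq = resid**2
        overall = float(np.sqrt(sq.mean()))
        by_type: dict[str, float] = {}
        for label in dict.fromkeys(d.row_labels):  # preserves schedule order
            mask = d.row_labels == label
            # Rest replicas are identical rows, so the per-type mean over the
            # replicated block equals the mean over unique frames.
            by_type[str(label)] = float(np.sqrt(sq[mask].mean()))
        return QualityReport(rmse_by_type=by_type, rmse_overall=overall)

    def summary(self) -> str:
        q = self.quality
        lines = [
            "EMGσ-force model (truncated-SVD pseudo-inverse least squares)",
            "=" * 62,
            f"strategy:            {self.strategy}",
            f"channels ({len(self.channels):2d}):       {self.channel_names}",
            f"bias column:         {self.bias_enabled}",
            f"SVD tolerance:       {self.tol_used}",
            f"singular retained:   {self.n_singular_retained}",
            "-" * 62,
            f"{'contraction type':<20s}{'RMSE (%MVC)':>12s}",
        ]
        for label, r in q.rmse_by_type.items():
            lines.append(f"{label:<20s}{r:>12.3f}")
        lines.append("-" * 62)
        lines.append(f"{'overall':<20s}{q.rmse_overall:>12.3f}")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Target vs. estimated force over the calibration design
        (requires matplotlib)."""
        import matplotlib.pyplot as plt

        d = self.model.design
        cols = list(self.channels) + ([d.n_channels] if d.bias else [])
        est = d.X[:, cols] @ self.coef
        if ax is None:
            _, ax = plt.subplots(2, 1, sharex=True, figsize=(9, 5))
        t = np.arange(d.Y.shape[0]) / 100.0
        for i, (a, name) in enumerate(zip(ax, ("hand", "wrist"))):
            a.plot(t, d.Y[:, i], lw=1.5, label="target")
            a.plot(t, est[:, i], lw=0.7, label="estimated")
            a.set_ylabel(f"{name} (%MVC)")
            a.legend(loc="upper right")
        ax[-1].set_xlabel("design row time (s)")
        return ax

    # -- serialisation ----------------------------------------------------

    def to_dict(self, created_utc: str | None = None, seed_provenance: str | None = None) -> dict:
        return {
            "strategy": self.strategy,
            "channels": list(map(int, self.channels)),
            "channel_names": list(self.channel_names),
            "coef": self.coef.tolist(),
            "coef_shape": list(self.coef.shape),
            "bias_enabled": bool(self.bias_enabled),
            "tol_used": float(self.tol_used),
            "n_singular_retained": int(self.n_singular_retained),
            "quality": {
                "rmse_by_type": self.quality.rmse_by_type,
                "rmse_overall": self.quality.rmse_overall,
            }
            if self.quality
            else None,
            "created_utc": created_utc,
            "seed_provenance": seed_provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EmgForceResults":
        q = d.get("quality")
        return cls(
            model=None,
            coef=np.array(d["coef"], dtype=np.float64),
            channels=list(d["channels"]),
            strategy=d["strategy"],
            tol_used=d["tol_used"],
            n_singular_retained=d["n_singular_retained"],
            bias_enabled=d["bias_enabled"],
            channel_names=list(d.get("channel_names", [])),
            quality=QualityReport(
                rmse_by_type=dict(q["rmse_by_type"]), rmse_overall=q["rmse_overall"]
            )
            if q
            else None,
        )


# -- functional wrappers ---------------------------------------------------

def fit_pseudo_inverse(design: DesignData, tol: float = 0.01, strategy: str = DIRCON) -> EmgForceResults:
    return EmgForceModel(design, strategy).fit(tol=tol)


def backward_select(design: DesignData, k: int, tol: float = 0.01, strategy: str = DIRCON) -> EmgForceResults:
    return EmgForceModel(design, strategy).select_channels(k, tol=tol)


def predict(results: EmgForceResults, sigma: SigmaSeries | np.ndarray) -> np.ndarray:
    return results.predict(sigma)


def quality_rmse(results: EmgForceResults) -> QualityReport:
    return results._compute_quality()
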