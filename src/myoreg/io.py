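"""File I/O: raw-EMG CSV, model JSON, configuration YAML/JSON.

Raw EMG CSV dialect: two header lines

    # fs_hz=<float>
    # channels=<comma-separated names>

followed by one row per sample, one column per channel, ``.`` decimal,
UTF-8.  All writers are atomic (write to a temporary file in the target
directory, then rename), so a failed run never leaves a partial artifact
behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import EmgForceResults
from .signal import RawEmg

__all__ = [
    "read_raw",
    "write_raw",
    "save_model",
    "load_model",
    "load_yaml",
    "atomic_write_text",
    "write_truth_csv",
]


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_raw(path: str | Path, raw: RawEmg, fmt: str = "%.10g") -> None:
    lines = [f"# fs_hz={raw.fs_hz:g}", "# channels=" + ",".join(raw.channel_names)]
    body = "\n".join(
        ",".join(fmt % v for v in row) for row in raw.samples
    )
    atomic_write_text(path, "\n".join(lines) + "\n" + body + "\n")


def read_raw(path: str | Path) -> RawEmg:
    """Parse the raw-EMG CSV dialect, with line/field context on errors."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        second = fh.readline().strip()
    if not first.startswith("# fs_hz="):
        raise ValueError(f"{path}: line 1 must be '# fs_hz=<float>', got {first!r}")
    try:
        fs = float(first.split("=", 1)[1])
    except ValueError as e:
        raise ValueError(f"{path}: line 1: cannot parse sampling rate: {e}") from e
    if not second.startswith("# channels="):
        raise ValueError(f"{path}: line 2 must be '# channels=<comma-list>', got {second!r}")
    channels = second.split("=", 1)[1].split(",")
    try:
        df = pd.read_csv(
            path, skiprows=2, header=None, dtype=np.float64, float_precision="round_trip"
        )
    except Exception as e:
        raise ValueError(f"{path}: data block is not numeric CSV: {e}") from e
    if df.shape[1] != len(channels):
        raise ValueError(
            f"{path}: {df.shape[1]} data columns but {len(channels)} declared channels"
        )
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: missing/non-numeric cell at data row {row}")
    return RawEmg(samples=df.to_numpy(), fs_hz=fs, channel_names=channels)


def write_truth_csv(path: str | Path, t_s: np.ndarray, force: np.ndarray) -> None:
    """Ground-truth force CSV: t_s, hand_pct, wrist_pct per frame."""
    lines = ["t_s,hand_pct,wrist_pct"]
    for t, (h, w) in zip(t_s, force):
        lines.append(f"{t:.3f},{h:.6g},{w:.6g}")
    atomic_write_text(path, "\n".join(lines) + "\n")


def save_model(
    path: str | Path,
    results: EmgForceResults,
    seed_provenance: str | None = None,
    timestamp: bool = True,
) -> None:
    """Serialise fitted results to JSON (lossless round-trip).

    ``timestamp=False`` omits the creation time so byte-level
    reproducibility comparisons ignore wall-clock metadata.
    """
    created = datetime.now(timezone.utc).isoformat() if timestamp else None
    d = results.to_dict(created_utc=created, seed_provenance=seed_provenance)
    atomic_write_text(path, json.dumps(d, indent=1))


def load_model(path: str | Path) -> EmgForceResults:
    with open(path, encoding="utf-8") as fh:
        return EmgForceResults.from_dict(json.load(fh))


def load_yaml(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return out
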