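"""CSV trace I/O emulating datalogger exports.

Dialect: header-keyed UTF-8 CSV with columns ``time_s, pressure_cmH2O,
flow_L_s, volume_mL, cycle_index`` (any column order), decimal point,
newline-terminated. A structured JSON sidecar (``<name>.meta.json``)
carries the sampling rate and a scenario config hash.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ventilator import PressureTrace

__all__ = ["write_trace", "read_trace", "TraceParseError"]

REQUIRED_COLUMNS = ("time_s", "pressure_cmH2O", "flow_L_s", "volume_mL")


class TraceParseError(ValueError):
    pass


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_trace(trace: PressureTrace, path, metadata: dict | None = None) -> Path:
    """Write a trace and its metadata sidecar; returns the CSV path."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "pressure_cmH2O": trace.pressure,
            "flow_L_s": trace.flow,
            "volume_mL": trace.volume,
            "cycle_index": trace.cycle_index,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {"sampling_rate_hz": trace.sampling_rate}
    if metadata:
        meta.update(metadata)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return path


def read_trace(path, step_tolerance: float = 1.5) -> PressureTrace:
    """Read a trace CSV; write∘read is identity to 1e-9 on all columns.

    Rejects files with missing columns or a time gap larger than
    ``step_tolerance`` times the median step, naming the offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise TraceParseError(f"{path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing required columns {missing}")
    bad = df[REQUIRED_COLUMNS[0]].isna()
    for c in REQUIRED_COLUMNS:
        bad |= df[c].isna()
    if bad.any():
        # +2: header line and 1-based numbering.
        lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]
        raise TraceParseError(f"{path}: malformed rows at lines {lines}")

    t = df["time_s"].to_numpy(float)
    steps = np.diff(t)
    if steps.size:
        med = float(np.median(steps))
        if med <= 0:
            raise TraceParseError(f"{path}: non-increasing time column")
        jump = steps > step_tolerance * med
        if jump.any():
            line = int(np.flatnonzero(jump)[0]) + 3  # row after the gap
            raise TraceParseError(
                f"{path}: time gap exceeding {step_tolerance}x the median "
                f"step at line {line}"
            )

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        fs = float(json.loads(sidecar.read_text())["sampling_rate_hz"])
    else:
        fs = 1.0 / float(np.median(steps)) if steps.size else 0.0

    cyc = (
        df["cycle_index"].to_numpy(int)
        if "cycle_index" in df.columns
        else np.zeros(len(df), dtype=int)
    )
    return PressureTrace(
        sampling_rate=fs,
        time=t,
        pressure=df["pressure_cmH2O"].to_numpy(float),
        flow=df["flow_L_s"].to_numpy(float),
        volume=df["volume_mL"].to_numpy(float),
        cycle_index=cyc,
    )
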