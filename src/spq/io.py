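"""Readers and writers for traces, event tables and configuration files.

The canonical trace dialect is a two-column CSV: a time column in seconds
(or a 0-based dwell index) and an integer counts column, with an optional
header.  Delimiter and column meaning can be overridden; vendor binary
formats are out of scope.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detect import EVENT_COLUMNS, DwellTrace

__all__ = [
    "read_trace",
    "write_trace",
    "read_event_table",
    "write_event_table",
    "load_config",
    "write_json_report",
]


class TraceFormatError(ValueError):
    """Raised for malformed trace files."""


def _has_header(path: Path, delimiter: str | None) -> bool:
    first = Path(path).open().readline()
    sep = delimiter or ","
    fields = [f.strip() for f in first.strip().split(sep)]
    for f in fields:
        try:
            float(f)
        except ValueError:
            return True
    return False


def read_trace(
    path,
    dwell_time: float | None = None,
    delimiter: str | None = None,
    element_label: str = "",
    acquisition_id: str | None = None,
) -> DwellTrace:
    """Read a two-column (time or dwell index, counts) CSV trace.

    The first column is interpreted as time in seconds when its spacing is
    consistent (within 1%) with a constant dwell; the dwell time is then
    inferred unless given.  Integer counts are enforced — non-integer values
    raise rather than being silently rounded.
    """
    path = Path(path)
    header = 0 if _has_header(path, delimiter) else None
    df = pd.read_csv(path, sep=delimiter or ",", header=header)
    if df.shape[1] != 2:
        raise TraceFormatError(f"{path}: expected 2 columns, found {df.shape[1]}")
    t, c = df.iloc[:, 0].to_numpy(dtype=float), df.iloc[:, 1].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)) or np.any(~np.isfinite(c)):
        raise TraceFormatError(f"{path}: malformed (non-numeric) rows")
    if not np.allclose(c, np.rint(c), atol=1e-9):
        raise TraceFormatError(f"{path}: counts column contains non-integer values")
    if np.any(c < 0):
        raise TraceFormatError(f"{path}: negative count values")

    if len(t) >= 2:
        spacing = np.diff(t)
        med = float(np.median(spacing))
        if med <= 0 or np.any(np.abs(spacing - med) > 0.01 * med):
            raise TraceFormatError(f"{path}: inconsistent time/index spacing")
        # an index column steps by exactly 1; a time column carries the dwell
        is_index = np.allclose(t, np.rint(t)) and med == 1.0
        if dwell_time is None:
            if is_index:
                raise TraceFormatError(
                    f"{path}: first column looks like a dwell index; pass dwell_time"
                )
            dwell_time = med
    elif dwell_time is None:
        raise TraceFormatError(f"{path}: cannot infer dwell time from one row")

    return DwellTrace(
        counts=np.rint(c).astype(np.int64),
        dwell_time=float(dwell_time),
        element_label=element_label,
        acquisition_id=acquisition_id if acquisition_id is not None else path.stem,
    )


def write_trace(path, trace: DwellTrace, time_column: bool = True) -> None:
    """Write a trace in the canonical two-column CSV dialect."""
    n = len(trace)
    first = (
        np.arange(n) * trace.dwell_time if time_column else np.arange(n)
    )
    df = pd.DataFrame(
        {("time_s" if time_column else "dwell_index"): first, "counts": trace.counts}
    )
    df.to_csv(path, index=False)


def read_event_table(path) -> pd.DataFrame:
    """Read an event table CSV (round-trips :func:`write_event_table`)."""
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing event columns {missing}")
    df["acquisition_id"] = df["acquisition_id"].astype(str)
    return df


def write_event_table(path, events: pd.DataFrame) -> None:
    events.to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML (or JSON) configuration file to a dict."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return _to_jsonable(
            {k: getattr(obj, k) for k in obj.__dataclass_fields__}
        )
    return obj


def write_json_report(path, report) -> None:
    """Serialise a report (dict/dataclass, numpy-friendly) as sorted JSON."""
    Path(path).write_text(
        json.dumps(_to_jsonable(report), indent=2, sort_keys=True) + "\n"
    )
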