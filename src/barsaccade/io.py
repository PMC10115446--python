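"""CSV/JSON readers and writers for the three trace kinds.

Traces are stored as plain CSV time series with a JSON sidecar (same stem,
``.json`` extension) carrying events and metadata.  Required columns:

* calcium:  ``t_s,value``
* heading:  ``t_s,heading_deg,bar_deg``
* steering: ``t_s,dwba_v,bar_deg``

Angles are serialized in degrees; a save -> load round trip preserves values
to better than 1e-9.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, SchemaError
from .types import CalciumTrace, HeadingTrace, SteeringTrace, StimulusEvent

__all__ = ["load_timeseries", "save_timeseries", "load_response_matrix", "save_response_matrix"]

_FLOAT_FMT = "%.12g"

_COLUMNS = {
    "calcium": ["t_s", "value"],
    "heading": ["t_s", "heading_deg", "bar_deg"],
    "steering": ["t_s", "dwba_v", "bar_deg"],
}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def load_timeseries(path, kind: str):
    """Load a typed trace from CSV (+ optional JSON sidecar).

    ``kind`` is one of 'calcium', 'heading', 'steering'.
    """
    if kind not in _COLUMNS:
        raise InvalidArgumentError(f"unknown trace kind {kind!r}")
    path = Path(path)
    df = pd.read_csv(path)
    for col in _COLUMNS[kind]:
        if col not in df.columns:
            raise SchemaError(f"column {col!r} required for kind={kind!r} missing in {path.name}")
    t = df["t_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise InvalidArgumentError(f"non-monotone time axis in {path.name}")
    side = _sidecar(path)
    extra = json.loads(side.read_text()) if side.exists() else {}
    if kind == "calcium":
        events = [StimulusEvent(*ev) for ev in extra.get("events", [])]
        return CalciumTrace(
            time_s=t,
            value=df["value"].to_numpy(dtype=float),
            events=events,
            is_dff=bool(extra.get("is_dff", False)),
        )
    if kind == "heading":
        return HeadingTrace(
            time_s=t,
            heading_deg=df["heading_deg"].to_numpy(dtype=float),
            bar_deg=df["bar_deg"].to_numpy(dtype=float),
            meta=extra.get("meta", {}),
        )
    return SteeringTrace(
        time_s=t,
        dwba=df["dwba_v"].to_numpy(dtype=float),
        bar_deg=df["bar_deg"].to_numpy(dtype=float),
        meta=extra.get("meta", {}),
    )


def save_timeseries(trace, path) -> Path:
    """Write a trace as CSV plus a JSON sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(trace, CalciumTrace):
        df = pd.DataFrame({"t_s": trace.time_s, "value": trace.value})
        extra = {
            "kind": "calcium",
            "is_dff": trace.is_dff,
            "events": [[e.label, e.onset_s, e.offset_s] for e in trace.events],
        }
    elif isinstance(trace, HeadingTrace):
        df = pd.DataFrame(
            {"t_s": trace.time_s, "heading_deg": trace.heading_deg, "bar_deg": trace.bar_deg}
        )
        extra = {"kind": "heading", "meta": trace.meta}
    elif isinstance(trace, SteeringTrace):
        df = pd.DataFrame(
            {"t_s": trace.time_s, "dwba_v": trace.dwba, "bar_deg": trace.bar_deg}
        )
        extra = {"kind": "steering", "meta": trace.meta}
    else:
        raise InvalidArgumentError(f"unsupported trace type {type(trace).__name__}")
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    _sidecar(path).write_text(json.dumps(extra, indent=1, sort_keys=True, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")


def save_response_matrix(matrix, path) -> Path:
    """ResponseMatrix as CSV: first column wavelength (deg), header row TF (Hz)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        matrix.amplitude,
        index=pd.Index(matrix.wavelengths_deg, name="wavelength_deg"),
        columns=[f"{tf:g}" for tf in matrix.tfs_hz],
    )
    df.to_csv(path, float_format=_FLOAT_FMT)
    return path


def load_response_matrix(path):
    """Inverse of :func:`save_response_matrix`."""
    from .types import ResponseMatrix

    df = pd.read_csv(Path(path), index_col=0)
    return ResponseMatrix(
        wavelengths_deg=df.index.to_numpy(dtype=float),
        tfs_hz=np.array([float(c) for c in df.columns]),
        amplitude=df.to_numpy(dtype=float),
    )
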