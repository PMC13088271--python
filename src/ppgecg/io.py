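"""On-disk formats: two-column delimited signals, JSON annotations and
metadata, CSV feature tables, and config sidecars for provenance.

Everything is plain text so artifacts stay diff-able at desk scale.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BeatAnnotation, FormatError, TimeSeries

__all__ = [
    "read_signal",
    "write_signal",
    "read_annotations",
    "write_annotations",
    "write_json",
    "read_json",
    "write_sidecar",
]


def write_signal(path, ts: TimeSeries) -> None:
    """Two-column delimited text: time_s, value."""
    data = np.column_stack([ts.times(), ts.samples])
    np.savetxt(path, data, fmt="%.9f %.12g", header="time_s value")


def read_signal(path) -> TimeSeries:
    """Read a two-column (time_s, value) text signal.

    Timestamps must be uniform to within 1 ppm of the median step; the first
    offending row is named otherwise.
    """
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns (time_s, value)")
    if data.shape[0] < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    t, x = data[:, 0], data[:, 1]
    dt = np.diff(t)
    dt0 = float(np.median(dt))
    if dt0 <= 0:
        raise FormatError(f"{path}: timestamps are not increasing")
    bad = np.flatnonzero(np.abs(dt - dt0) > 1e-6 * dt0)
    if bad.size:
        row = int(bad[0]) + 1
        raise FormatError(
            f"{path}: non-uniform sampling at row {row} "
            f"(step {dt[bad[0]]:.9f} s vs {dt0:.9f} s)"
        )
    return TimeSeries(x, fs=1.0 / dt0, t0=float(t[0]))


def write_annotations(path, annotations: list[BeatAnnotation]) -> None:
    payload = [
        {"r_time": a.r_time, "onset_time": a.onset_time, "peak_time": a.peak_time}
        for a in annotations
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotations(path) -> list[BeatAnnotation]:
    payload = json.loads(Path(path).read_text())
    return [
        BeatAnnotation(
            r_time=row["r_time"],
            onset_time=row["onset_time"],
            peak_time=row["peak_time"],
        )
        for row in payload
    ]


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_coerce))


def read_json(path):
    return json.loads(Path(path).read_text())


def _coerce(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_sidecar(artifact_path, config) -> None:
    """Drop ``<artifact>.config.json`` with the exact RunConfig used."""
    p = Path(str(artifact_path) + ".config.json")
    p.write_text(config.to_json())
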