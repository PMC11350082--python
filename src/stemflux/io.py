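"""CSV I/O in the shared column dialect, with schema validation.

All tabular artifacts are plain CSV with ISO-8601 timestamps in a ``timestamp``
column.  Readers validate the declared schema, report violations with row
numbers, sort shuffled files with a warning, and preserve unknown columns.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd

from .errors import LoadError

DRIVER_SCHEMA = ("temp", "ppfd", "rh", "sapflux", "co2_ambient")
FLUX_SCHEMA = ("fco2", "chamber", "tree", "flags")


def read_timeseries(path, required: tuple[str, ...]) -> pd.DataFrame:
    """Load a timestamp-indexed CSV and validate its schema.

    Raises :class:`LoadError` naming any missing column, any unparseable
    timestamp (with its row number) and non-monotone duplicated timestamps;
    out-of-order rows are sorted with a warning.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if "timestamp" not in frame.columns:
        raise LoadError(f"{path.name}: missing required column 'timestamp'")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise LoadError(f"{path.name}: missing required column(s) {missing}")
    stamps = pd.to_datetime(frame["timestamp"], errors="coerce", format="ISO8601")
    bad = stamps.isna()
    if bad.any():
        rows = [int(i) + 2 for i in frame.index[bad][:5]]  # +2: header + 0-base
        raise LoadError(f"{path.name}: unparseable timestamp at file row(s) {rows}")
    frame = frame.drop(columns=["timestamp"]).set_index(pd.DatetimeIndex(
        stamps, name="timestamp"))
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()][:3]
        raise LoadError(f"{path.name}: duplicated timestamps, e.g. {list(dupes)}")
    if not frame.index.is_monotonic_increasing:
        warnings.warn(f"{path.name}: rows out of order; sorted on load", stacklevel=2)
        frame = frame.sort_index()
    if "flags" in frame.columns:
        frame["flags"] = frame["flags"].fillna("")
    return frame


def write_timeseries(frame: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = frame.copy()
    out.index = out.index.strftime("%Y-%m-%dT%H:%M:%S")
    out.index.name = "timestamp"
    out.to_csv(path)
    return path


def write_json(payload: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return path


def traces_to_frame(traces: list) -> pd.DataFrame:
    """Long-format closure traces (closure_id, t_s, co2_ppm) for CSV export."""
    rows = []
    for tr in traces:
        for t, c in zip(tr.t_s, tr.co2_ppm):
            rows.append({"closure_id": tr.closure_id, "chamber_id": tr.chamber_id,
                         "start_time": tr.start_time, "t_s": t, "co2_ppm": c,
                         "c_in_ppm": tr.c_in_ppm,
                         "chamber_air_temp_c": tr.chamber_air_temp_c,
                         "pressure_kpa": tr.pressure_kpa})
    return pd.DataFrame(rows)
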