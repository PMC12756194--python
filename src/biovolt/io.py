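"""Readers and writers for traces, events and summary tables.

Formats are deliberately plain for cross-language interchange: comma-separated
CSV, '.' decimal, UTF-8, LF line endings. Times are serialized in seconds with
6 decimals, voltages in µV with 3 decimals; writers and readers are lossless
inverses at that precision. Each trace CSV (``time_s,voltage_uV``) carries a
JSON sidecar ``<stem>.meta.json`` with sampling rate, condition label, day
index, seed and units. Units must be ``"uV"`` — anything else is rejected
rather than silently rescaled.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    MissingSidecarError,
    NonUniformSamplingError,
    UnitMismatchError,
)
from .types import (
    EventRecord,
    QuartileSummary,
    TraceMeta,
    VoltageTrace,
    check_sorted,
)

#: Relative tolerance on the time column's sampling uniformity.
_JITTER_TOL = 1e-6

EVENT_COLUMNS = ("onset_s", "event_class", "amplitude_uV", "duration_s")
SUMMARY_COLUMNS = ("condition",
                   "freq_q2", "freq_iqr_lo", "freq_iqr_hi", "freq_q4",
                   "amp_q2", "amp_iqr_lo", "amp_iqr_hi", "amp_q4")


def sidecar_path(trace_path) -> Path:
    p = Path(trace_path)
    return p.with_name(p.stem + ".meta.json")


def write_trace(path, trace: VoltageTrace) -> Path:
    """Write a trace CSV and its JSON metadata sidecar; returns the CSV path."""
    path = Path(path)
    t = trace.times
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("time_s,voltage_uV\n")
        np.savetxt(fh, np.column_stack([t, trace.samples]),
                   fmt=("%.6f", "%.3f"), delimiter=",", newline="\n")
    meta = {
        "fs_hz": trace.meta.fs_hz,
        "condition": trace.meta.condition,
        "day_index": trace.meta.day_index,
        "seed": trace.meta.seed,
        "units": trace.meta.units,
        **({"extra": trace.meta.extra} if trace.meta.extra else {}),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1) + "\n", encoding="utf-8")
    return path


def read_trace(path) -> VoltageTrace:
    """Read a trace CSV + sidecar, validating units and sampling uniformity.

    The time column must be uniform at the sidecar's ``fs_hz`` with relative
    jitter below 1e-6 of the sampling interval span.
    """
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise MissingSidecarError(f"no metadata sidecar {side} for trace {path}")
    meta_d = json.loads(side.read_text(encoding="utf-8"))
    units = meta_d.get("units", "uV")
    if units != "uV":
        raise UnitMismatchError(f"trace units must be 'uV', sidecar declares {units!r}")
    meta = TraceMeta(fs_hz=float(meta_d["fs_hz"]), condition=str(meta_d["condition"]),
                     day_index=int(meta_d.get("day_index", 1)),
                     seed=meta_d.get("seed"), units=units,
                     extra=meta_d.get("extra", {}))

    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    v = df["voltage_uV"].to_numpy(dtype=float)
    if t.size >= 2:
        dt = np.diff(t)
        expected = 1.0 / meta.fs_hz
        if np.any(np.abs(dt - expected) > _JITTER_TOL * max(expected, 1.0)):
            raise NonUniformSamplingError(
                f"time column of {path} is not uniform at fs={meta.fs_hz} Hz")
    return VoltageTrace(fs_hz=meta.fs_hz, samples=v, meta=meta)


def write_events(path, events: Sequence[EventRecord]) -> Path:
    """Write an event CSV (fixed column order); events must be onset-sorted."""
    check_sorted(events)
    path = Path(path)
    df = pd.DataFrame(
        [(e.onset_s, e.event_class, e.peak_amp_uv, e.duration_s) for e in events],
        columns=list(EVENT_COLUMNS))
    df.to_csv(path, index=False, lineterminator="\n",
              float_format="%.6f", encoding="utf-8")
    return path


def read_events(path) -> list[EventRecord]:
    df = pd.read_csv(path)
    return [EventRecord(onset_s=float(r.onset_s), peak_amp_uv=float(r.amplitude_uV),
                        duration_s=float(r.duration_s), event_class=str(r.event_class))
            for r in df.itertuples(index=False)]


def write_state(path, state: np.ndarray) -> Path:
    """Optional per-sample telegraph state as a one-column CSV (gzip if *.gz)."""
    path = Path(path)
    pd.DataFrame({"rts_state": np.asarray(state, dtype=np.int8)}).to_csv(
        path, index=False, lineterminator="\n", encoding="utf-8")
    return path


def summary_to_frame(rows: Iterable[QuartileSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.condition, r.freq_q2, r.freq_iqr_lo, r.freq_iqr_hi, r.freq_q4,
          r.amp_q2, r.amp_iqr_lo, r.amp_iqr_hi, r.amp_q4) for r in rows],
        columns=list(SUMMARY_COLUMNS))


def write_summary(path, rows) -> Path:
    """Write the per-condition summary CSV (one row per condition)."""
    path = Path(path)
    df = rows if isinstance(rows, pd.DataFrame) else summary_to_frame(rows)
    df.to_csv(path, index=False, lineterminator="\n",
              float_format="%.6f", encoding="utf-8")
    return path


def read_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary file {path} lacks columns {sorted(missing)}")
    return df
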