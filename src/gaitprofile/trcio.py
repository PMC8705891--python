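"""Readers/writers for the interchange formats the pipeline touches.

TRC is written in the OpenSim dialect: two tab-separated header blocks
(``PathFileType`` line, then ``DataRate ... Units`` keys and values), a
``Frame#\\tTime`` column header with one marker label per X/Y/Z triplet, and
numeric rows.  Angles are stored in degrees in all outputs and radians
internally; the unit boundary is this module.  Marker positions follow the
laboratory frame X = progression, Y = left, Z = up.

Gait events and cohort metadata travel as sidecar CSV files (TRC has no
event block), coordinate trajectories as MOT-compatible column files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .metrics import GaitCycleWaveforms
from .trial import MarkerTrial


class ParseError(ValidationError):
    """Malformed interchange file; message carries the 1-based line number."""


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------

def write_trc(trial: MarkerTrial, path, units: str = "mm") -> None:
    """Write a trial as OpenSim-dialect TRC (default millimetres)."""
    if units not in ("mm", "m"):
        raise ValidationError(f"unsupported TRC units {units!r}")
    factor = 1000.0 if units == "mm" else 1.0
    labels = list(trial.markers)
    n = trial.n_frames
    rate = trial.rate
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{rate:.6f}\t{rate:.6f}\t{n}\t{len(labels)}\t{units}\t"
                 f"{rate:.6f}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(labels) + "\t\t\t\n")
        fh.write("\t\t" + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(labels)))
                 + "\n")
        for i in range(n):
            row = [str(i + 1), f"{trial.time[i]:.8f}"]
            for lab in labels:
                row.extend(f"{v * factor:.8f}" for v in trial.markers[lab][i])
            fh.write("\t".join(row) + "\n")


def read_trc(path, events: dict | None = None, meta: dict | None = None) -> MarkerTrial:
    """Read an OpenSim-dialect TRC file; positions converted to metres."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise ParseError(f"{path.name}: truncated TRC file ({len(lines)} lines)")
    header_keys = lines[1].rstrip("\n").split("\t")
    header_vals = lines[2].rstrip("\n").split("\t")
    header = dict(zip(header_keys, header_vals))
    try:
        n_frames = int(header["NumFrames"])
        n_markers = int(header["NumMarkers"])
        units = header["Units"]
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path.name}: malformed TRC header at line 3 ({exc})") from exc
    if units not in ("mm", "m"):
        raise ParseError(f"{path.name}: unsupported units {units!r} at line 3")
    factor = 0.001 if units == "mm" else 1.0

    labels = [lab for lab in lines[3].rstrip("\n").split("\t")[2:] if lab]
    if len(labels) != n_markers:
        raise ParseError(f"{path.name}: line 4 lists {len(labels)} markers, "
                         f"header says {n_markers}")

    data_lines = [ln for ln in lines[5:] if ln.strip()]
    if len(data_lines) != n_frames:
        raise ParseError(f"{path.name}: {len(data_lines)} data rows from line 6, "
                         f"header says {n_frames}")
    times = np.empty(n_frames)
    coords = np.empty((n_frames, n_markers * 3))
    for i, ln in enumerate(data_lines):
        parts = ln.split("\t")
        if len(parts) < 2 + 3 * n_markers:
            raise ParseError(f"{path.name}: short data row at line {6 + i}")
        try:
            times[i] = float(parts[1])
            coords[i] = [float(x) for x in parts[2:2 + 3 * n_markers]]
        except ValueError as exc:
            raise ParseError(f"{path.name}: bad numeric value at line {6 + i}") from exc
    markers = {lab: coords[:, 3 * k:3 * k + 3] * factor for k, lab in enumerate(labels)}
    return MarkerTrial(time=times, markers=markers, events=events or {},
                       meta=dict(meta or {}, source=str(path)))


# ---------------------------------------------------------------------------
# Events / MOT / waveform CSV
# ---------------------------------------------------------------------------

def write_events_csv(trial: MarkerTrial, path) -> None:
    rows = [{"side": side, "kind": kind, "time": t}
            for side, evs in trial.events.items()
            for kind, ts in evs.items() for t in ts]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_events_csv(path) -> dict:
    df = pd.read_csv(path)
    events: dict = {}
    for (side, kind), sub in df.groupby(["side", "kind"]):
        events.setdefault(side, {})[kind] = sorted(sub["time"].tolist())
    return events


def write_mot(path, time: np.ndarray, columns: dict[str, np.ndarray],
              name: str = "coordinates", in_degrees: bool = True) -> None:
    """Write a time-series table in MOT/STO column format (angles degrees)."""
    time = np.asarray(time, float)
    n = time.size
    for key, col in columns.items():
        if np.asarray(col).shape != (n,):
            raise ValidationError(f"MOT column {key} length mismatch")
    with open(path, "w") as fh:
        fh.write(f"{name}\nversion=1\nnRows={n}\nnColumns={1 + len(columns)}\n"
                 f"inDegrees={'yes' if in_degrees else 'no'}\nendheader\n")
        fh.write("time\t" + "\t".join(columns) + "\n")
        for i in range(n):
            fh.write(f"{time[i]:.8f}\t"
                     + "\t".join(f"{np.asarray(c)[i]:.8f}" for c in columns.values()) + "\n")


def waveforms_to_frame(waveforms: list[GaitCycleWaveforms]) -> pd.DataFrame:
    """Tidy long table: subject, session, engine, side, cycle, variable,
    percent (0..100), value (degrees)."""
    rows = []
    for w in waveforms:
        pct = np.linspace(0, 100, w.T)
        for i, var in enumerate(w.variables):
            rows.append(pd.DataFrame({
                "subject": w.meta.get("subject", ""),
                "session": w.meta.get("session", ""),
                "engine": w.meta.get("engine", ""),
                "side": w.side, "cycle": w.cycle_id, "variable": var,
                "percent": pct, "value": w.values[i],
            }))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["subject", "session", "engine", "side", "cycle",
                 "variable", "percent", "value"])


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
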