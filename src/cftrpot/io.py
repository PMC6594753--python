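"""Plain-text file formats: traces, event lists, dose-response tables.

Traces are two-column delimited text (time_s, value) with optional
``#``-prefixed header lines of the form ``# key: value``; the ``protocol``
key holds the drug protocol as JSON.  Event lists are two-column
(level, duration_s) with ``dead_time_s`` and ``n_channels`` headers.
Round trips are lossless at full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .gating import EventList
from .response import DoseResponsePoint
from .schemes import DrugProtocol

__all__ = [
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "read_dose_response",
    "write_dose_response",
]


def _parse_two_columns(path: Path) -> tuple[np.ndarray, np.ndarray, dict]:
    meta: dict[str, str] = {}
    col1, col2 = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                col1.append(float(parts[0]))
                col2.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    return np.array(col1), np.array(col2), meta


def read_trace(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a (t, value) trace file.

    Returns ``(t, value, metadata)``; if a ``protocol`` header is present it
    is decoded into a :class:`DrugProtocol` under ``metadata["protocol"]``.
    """
    t, y, meta = _parse_two_columns(Path(path))
    if "protocol" in meta:
        meta["protocol"] = DrugProtocol.from_json_obj(json.loads(meta["protocol"]))
    return t, y, meta


def write_trace(path, t, y, metadata: dict | None = None) -> None:
    """Write a (t, value) trace with ``#`` metadata headers."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            if isinstance(value, DrugProtocol):
                value = json.dumps(value.to_json_obj())
            fh.write(f"# {key}: {value}\n")
        for ti, yi in zip(t, y):
            fh.write(f"{float(ti)!r}\t{float(yi)!r}\n")


def read_events(path) -> EventList:
    levels, durations, meta = _parse_two_columns(Path(path))
    return EventList(
        levels=levels.astype(int),
        durations=durations,
        dead_time=float(meta.get("dead_time_s", 6e-3)),
        n_channels=int(meta.get("n_channels", 1)),
    )


def write_events(path, events: EventList) -> None:
    with open(path, "w") as fh:
        fh.write(f"# dead_time_s: {float(events.dead_time)!r}\n")
        fh.write(f"# n_channels: {events.n_channels}\n")
        for lv, du in zip(events.levels, events.durations):
            fh.write(f"{int(lv)}\t{float(du)!r}\n")


def read_dose_response(path) -> list[DoseResponsePoint]:
    """Read a delimited dose-response table: conc_M, stimulation[, sem, n]."""
    points = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
            try:
                conc, stim = float(parts[0]), float(parts[1])
                sem = float(parts[2]) if len(parts) > 2 else None
                n = int(parts[3]) if len(parts) > 3 else None
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
            points.append(DoseResponsePoint(conc=conc, stimulation=stim, sem=sem, n=n))
    return points


def write_dose_response(path, points) -> None:
    with open(path, "w") as fh:
        fh.write("# conc_M\tstimulation\tsem\tn\n")
        for p in points:
            sem = "nan" if p.sem is None else repr(float(p.sem))
            n = 0 if p.n is None else p.n
            fh.write(f"{float(p.conc)!r}\t{float(p.stimulation)!r}\t{sem}\t{n}\n")
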