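"""Containers and delimited-text I/O for event logs and photometry traces.

Event logs are one row per timestamped event with columns
``mouse_id, group, session_type, test_index, event, time_s`` where ``event``
is one of ``ds_on, ds_off, operant, feeder, pellet``.  Traces are uniform-rate
fluorescence sample arrays with a session-aligned time zero; they are written
either as two-column CSV (``time_s,F``) or as an HDF5 container with one
dataset per mouse-session and a ``rate_hz`` attribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "EVENT_TYPES",
    "EventLog",
    "PhotometryTrace",
    "MalformedLogError",
    "read_events",
    "write_events",
    "read_trace_csv",
    "write_trace_csv",
    "read_trace_h5",
    "write_trace_h5",
]

EVENT_TYPES = ("ds_on", "ds_off", "operant", "feeder", "pellet")

EVENT_COLUMNS = ["mouse_id", "group", "session_type", "test_index", "event", "time_s"]


class MalformedLogError(ValueError):
    """Raised when an event log violates the session structure."""


@dataclass
class EventLog:
    """Ordered, timestamped behavioural events for one mouse-session."""

    mouse_id: str
    group: str
    session_type: str  # "DRLM" | "REV"
    test_index: int
    events: pd.DataFrame  # columns: event, time_s (sorted, strictly increasing)
    #: per-trial ground truth attached by the generator (not serialized)
    truth: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        ev = self.events
        if list(ev.columns) != ["event", "time_s"]:
            ev = ev[["event", "time_s"]]
        self.events = ev.reset_index(drop=True)

    def validate(self) -> None:
        t = self.events["time_s"].to_numpy()
        if len(t) and np.any(np.diff(t) <= 0):
            raise MalformedLogError(
                f"{self.mouse_id}/{self.session_type}{self.test_index}: "
                "event times are not strictly increasing"
            )
        bad = set(self.events["event"]) - set(EVENT_TYPES)
        if bad:
            raise MalformedLogError(f"unknown event types: {sorted(bad)}")

    def to_frame(self) -> pd.DataFrame:
        out = self.events.copy()
        out.insert(0, "test_index", self.test_index)
        out.insert(0, "session_type", self.session_type)
        out.insert(0, "group", self.group)
        out.insert(0, "mouse_id", self.mouse_id)
        return out

    @property
    def duration_s(self) -> float:
        return float(self.events["time_s"].iloc[-1]) if len(self.events) else 0.0


def write_events(logs: EventLog | list[EventLog], path: str | Path) -> None:
    """Write one or more event logs to a single CSV file."""
    if isinstance(logs, EventLog):
        logs = [logs]
    pd.concat([log.to_frame() for log in logs], ignore_index=True).to_csv(
        path, index=False
    )


def read_events(path: str | Path) -> list[EventLog]:
    """Read event logs from CSV, one :class:`EventLog` per mouse-session."""
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise MalformedLogError(f"event CSV missing columns: {sorted(missing)}")
    out = []
    keys = ["mouse_id", "group", "session_type", "test_index"]
    for (mouse, group, stype, test), sub in df.groupby(keys, sort=True):
        log = EventLog(
            mouse_id=str(mouse),
            group=str(group),
            session_type=str(stype),
            test_index=int(test),
            events=sub[["event", "time_s"]].sort_values("time_s"),
        )
        log.validate()
        out.append(log)
    return out


@dataclass
class PhotometryTrace:
    """Uniform-rate fluorescence samples F(t) with session-aligned time zero."""

    F: np.ndarray
    rate_hz: float
    t0: float = 0.0

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.F.size) / self.rate_hz

    @property
    def duration_s(self) -> float:
        return self.F.size / self.rate_hz


def write_trace_csv(trace: PhotometryTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.t, "F": trace.F}).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> PhotometryTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("trace needs at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trace sample times are not uniform")
    return PhotometryTrace(F=df["F"].to_numpy(float), rate_hz=1.0 / dt[0], t0=t[0])


def write_trace_h5(
    traces: dict[str, PhotometryTrace], path: str | Path, mode: str = "w"
) -> None:
    """Write traces keyed by ``mouse/session`` dataset names into HDF5."""
    with h5py.File(path, mode) as fh:
        for name, trace in traces.items():
            ds = fh.create_dataset(name, data=trace.F)
            ds.attrs["rate_hz"] = trace.rate_hz
            ds.attrs["t0"] = trace.t0


def read_trace_h5(path: str | Path, name: str | None = None):
    """Read one dataset (``name``) or all datasets from an HDF5 container."""
    with h5py.File(path, "r") as fh:
        names = []
        fh.visit(lambda n: names.append(n) if isinstance(fh[n], h5py.Dataset) else None)
        if name is not None:
            ds = fh[name]
            return PhotometryTrace(
                F=ds[()], rate_hz=float(ds.attrs["rate_hz"]),
                t0=float(ds.attrs.get("t0", 0.0)),
            )
        return {
            n: PhotometryTrace(
                F=fh[n][()], rate_hz=float(fh[n].attrs["rate_hz"]),
                t0=float(fh[n].attrs.get("t0", 0.0)),
            )
            for n in names
        }
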