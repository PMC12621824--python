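"""Plain-text readers and writers for the pipeline's input formats.

Event logs are tab-delimited (timestamp, event_type, context), one record per
line with a header. Spike trains are one text file of ascending spike times
per unit plus a ground-truth transitions table when generated synthetically.
Photometry traces are tab-delimited (time, signal_470, isosbestic_405).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .photometry import PhotometryTrace
from .synthetic_data import SessionEvents, SpikeTrainSet

__all__ = [
    "write_events", "read_events",
    "write_spike_trains", "read_spike_trains",
    "write_photometry", "read_photometry",
]


def write_events(events: SessionEvents, path) -> None:
    events.records.to_csv(path, sep="\t", index=False, float_format="%.6f",
                          columns=["time", "event", "context"])


def read_events(path, session_id: str | None = None, config=None) -> SessionEvents:
    records = pd.read_csv(path, sep="\t", dtype={"time": float, "event": str,
                                                 "context": str})
    ev = SessionEvents(records, session_id=session_id or Path(path).stem, config=config)
    ev.validate()
    return ev


def write_spike_trains(sts: SpikeTrainSet, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for unit, times in sts.spikes.items():
        np.savetxt(d / f"unit_{unit}.txt", times, fmt="%.6f")
    if sts.transitions is not None and len(sts.transitions):
        sts.transitions.to_csv(d / "transitions.tsv", sep="\t", index=False,
                               float_format="%.6f")


def read_spike_trains(directory) -> SpikeTrainSet:
    d = Path(directory)
    spikes = {}
    for f in sorted(d.glob("unit_*.txt")):
        unit = int(f.stem.split("_", 1)[1])
        spikes[unit] = np.atleast_1d(np.loadtxt(f, dtype=float))
    tfile = d / "transitions.tsv"
    transitions = pd.read_csv(tfile, sep="\t") if tfile.exists() else pd.DataFrame(
        columns=["unit", "visit", "epoch", "time", "kind"]
    )
    return SpikeTrainSet(spikes=spikes, transitions=transitions)


def write_photometry(trace: PhotometryTrace, path) -> None:
    pd.DataFrame(
        {"time": trace.time, "signal_470": trace.raw_470,
         "isosbestic_405": trace.raw_405}
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_photometry(path, session_id: str | None = None) -> PhotometryTrace:
    df = pd.read_csv(path, sep="\t")
    t = df["time"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    return PhotometryTrace(
        time=t, raw_470=df["signal_470"].to_numpy(),
        raw_405=df["isosbestic_405"].to_numpy(),
        sampling_rate=round(fs, 6), session_id=session_id or Path(path).stem,
    )
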