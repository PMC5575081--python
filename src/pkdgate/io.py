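"""CSV interchange for sweep traces and tabular results.

Canonical long-form trace format (UTF-8, '.' decimal):

    sweep_id,time_ms,voltage_mV,current_pA_per_pF[,x][,extra...]

Unknown columns are preserved on a read/write round trip.  Units are
embedded in column names throughout the package: voltages in mV, times in
ms, whole-cell current densities in pA/pF, unitary currents in pA.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .protocols import SweepProtocol, VoltageSegment
from .simulate import TraceSet

__all__ = ["read_traces", "write_traces"]

REQUIRED_COLUMNS = ("sweep_id", "time_ms", "voltage_mV", "current_pA_per_pF")


def write_traces(traces: TraceSet, path: str | Path) -> None:
    """Write a TraceSet as long-form CSV."""
    traces.to_frame().to_csv(path, index=False)


def _protocol_from_frame(groups, dt: float) -> SweepProtocol:
    # Reconstruct a minimal step protocol from sampled voltages: consecutive
    # runs of constant voltage become step segments (ramps are not inferred).
    sweeps = []
    for _, df in groups:
        v = df["voltage_mV"].to_numpy()
        change = np.flatnonzero(np.diff(v) != 0)
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [v.size]))
        segs = tuple(
            VoltageSegment.step(float(v[s]), dt * (e - s)) for s, e in zip(starts, ends)
        )
        sweeps.append(segs)
    holding = float(sweeps[0][0].level_start) if sweeps else 0.0
    return SweepProtocol("loaded", holding, tuple(sweeps), dt)


def read_traces(path: str | Path) -> TraceSet:
    """Read a long-form trace CSV into a TraceSet.

    Raises ``ValueError`` naming any missing mandatory column, and on
    non-monotone time within a sweep.  Tolerates CRLF line endings and
    trailing blank lines (pandas CSV dialect handling).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    groups = list(df.groupby("sweep_id", sort=True))
    time, volt, curr = [], [], []
    xs = [] if "x" in df.columns else None
    extra_names = [c for c in df.columns if c not in REQUIRED_COLUMNS + ("x",)]
    extras: dict[str, list[np.ndarray]] = {c: [] for c in extra_names}
    for sweep_id, sub in groups:
        t = sub["time_ms"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"non-monotone time within sweep {sweep_id}")
        time.append(t)
        volt.append(sub["voltage_mV"].to_numpy(dtype=float))
        curr.append(sub["current_pA_per_pF"].to_numpy(dtype=float))
        if xs is not None:
            xs.append(sub["x"].to_numpy(dtype=float))
        for c in extra_names:
            extras[c].append(sub[c].to_numpy())
    dt = float(np.median(np.diff(time[0]))) if time and time[0].size > 1 else 0.01
    protocol = _protocol_from_frame(groups, dt)
    return TraceSet(
        protocol=protocol,
        channel="loaded",
        time=time,
        voltage=volt,
        current=curr,
        x=xs,
        extras=extras,
    )
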