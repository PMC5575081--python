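"""Macroscopic current simulation over voltage-clamp protocols.

The whole-cell current density is

    I(t) = g_max * SF(V) * x(t) * (V - E_rev)        [pA/pF]

with the gating variable x integrated by forward Euler (dt = 0.01 ms by
default, x(0) = 0 at the start of every sweep) and SF(V) the rectification
scaling factor on the maximal conductance.  Step segments use the exact
solution of the Euler recursion; ramp segments update sample by sample
against the instantaneous command voltage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gating import euler_constant_voltage, steady_state_activation, time_constant
from .params import ChannelModel
from .protocols import SweepProtocol, VoltageSegment
from .rectification import scaling_factor

__all__ = ["TraceSet", "simulate_protocol", "steady_state_current"]

_log = logging.getLogger(__name__)


@dataclass
class TraceSet:
    """Simulated (or loaded) sweeps: time, command voltage, current, gating.

    All per-sweep arrays share a uniform time grid with spacing
    ``protocol.dt`` starting at 0.  ``extras`` carries any additional
    columns round-tripped through CSV untouched.
    """

    protocol: SweepProtocol
    channel: str
    time: list[np.ndarray]
    voltage: list[np.ndarray]
    current: list[np.ndarray]
    x: list[np.ndarray] | None = None
    model: ChannelModel | None = None
    extras: dict[str, list[np.ndarray]] = field(default_factory=dict)

    @property
    def n_sweeps(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: sweep_id, time_ms, voltage_mV, current_pA_per_pF[, x]."""
        frames = []
        for k in range(self.n_sweeps):
            d = {
                "sweep_id": np.full(self.time[k].size, k, dtype=int),
                "time_ms": self.time[k],
                "voltage_mV": self.voltage[k],
                "current_pA_per_pF": self.current[k],
            }
            if self.x is not None:
                d["x"] = self.x[k]
            for name, arrs in self.extras.items():
                d[name] = arrs[k]
            frames.append(pd.DataFrame(d))
        return pd.concat(frames, ignore_index=True)


def _segment_samples(seg: VoltageSegment, dt: float) -> int:
    n_exact = seg.duration / dt
    n = int(round(n_exact))
    if abs(n_exact - n) > 1e-9:
        _log.warning(
            "segment duration %.6g ms is not a multiple of dt=%.6g ms; "
            "rounded to %d samples", seg.duration, dt, n,
        )
    if n < 1:
        raise ValueError(
            f"segment duration {seg.duration} ms shorter than dt {dt} ms"
        )
    return n


def _segment_voltage(seg: VoltageSegment, n: int) -> np.ndarray:
    if seg.kind == "step":
        return np.full(n, seg.level_start)
    return seg.level_start + (seg.level_end - seg.level_start) * np.arange(n) / n


def simulate_protocol(
    protocol: SweepProtocol,
    model: ChannelModel,
    *,
    apply_scaling_factor: bool = True,
) -> TraceSet:
    """Integrate the gating model along every sweep of a protocol.

    Deterministic: identical inputs give bit-identical output.  The gating
    variable starts at 0 in every sweep.  Set ``apply_scaling_factor=False``
    to drop the rectification multiplier (SF ≡ 1).
    """
    dt = protocol.dt
    consts = model.constants
    times, volts, currents, xs = [], [], [], []
    for sweep in protocol.sweeps:
        v_parts, x_parts = [], []
        x = 0.0
        for seg in sweep:
            n = _segment_samples(seg, dt)
            v_seg = _segment_voltage(seg, n)
            if seg.kind == "step":
                x_seg = euler_constant_voltage(
                    x, float(seg.level_start), n, dt, model.activation, model.tau
                )
            else:
                x_seg = np.empty(n)
                for k in range(n):
                    vk = float(v_seg[k])
                    tau = time_constant(vk, model.tau)
                    x_inf = steady_state_activation(vk, model.activation)
                    x = min(1.0, max(0.0, x + dt * (x_inf - x) / tau))
                    x_seg[k] = x
            x = float(x_seg[-1]) if n else x
            v_parts.append(v_seg)
            x_parts.append(x_seg)
        v_all = np.concatenate(v_parts)
        x_all = np.concatenate(x_parts)
        t_all = dt * np.arange(v_all.size)
        sf = (
            scaling_factor(v_all, model.rectification)
            if apply_scaling_factor
            else 1.0
        )
        i_all = consts.g_max * sf * x_all * (v_all - consts.e_rev)
        times.append(t_all)
        volts.append(v_all)
        currents.append(i_all)
        xs.append(x_all)
    return TraceSet(
        protocol=protocol,
        channel=model.channel,
        time=times,
        voltage=volts,
        current=currents,
        x=xs,
        model=model,
    )


def steady_state_current(v, model: ChannelModel, *, apply_scaling_factor: bool = True):
    """Steady-state current density I_ss(V) = g_max SF(V) x_inf(V) (V - E_rev)."""
    arr = np.asarray(v, dtype=float)
    sf = scaling_factor(arr, model.rectification) if apply_scaling_factor else 1.0
    x_inf = steady_state_activation(arr, model.activation)
    out = model.constants.g_max * sf * x_inf * (arr - model.constants.e_rev)
    return out if arr.ndim else float(out)
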