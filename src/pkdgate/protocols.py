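"""Voltage-clamp protocol definitions.

Protocols are data: lists of per-sweep voltage segments (steps or ramps)
on a common holding potential and sample interval.  The built-in families
reproduce the study designs:

activation    hold -100 mV; 40-ms test steps from -100 to +300 mV in 20-mV
              increments (21 sweeps; extending v_max to +400 mV gives 26);
              tail at -100 mV.
inactivation  3-s conditioning steps from -100 to +140 mV in 20-mV
              increments (13 sweeps); 40-ms test at +120 mV; tail -100 mV.
recovery      1-s conditioning at +140 mV; recovery gap at the -100 mV
              holding potential of 0.1–20.1 s; 40-ms test at +140 mV.
ramp          voltage ramp from -100 to +180 mV.

The 30-s inter-sweep interval of the experimental designs is carried as an
annotation only: the model has no inactivated state to recover from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoltageSegment", "SweepProtocol", "build_protocol"]


@dataclass(frozen=True)
class VoltageSegment:
    """One command-voltage segment: a step or a linear ramp."""

    kind: str  # "step" | "ramp"
    level_start: float
    level_end: float
    duration: float  # ms

    def __post_init__(self) -> None:
        if self.kind not in ("step", "ramp"):
            raise ValueError(f"kind must be 'step' or 'ramp', got {self.kind!r}")
        if not (self.duration > 0):
            raise ValueError("duration must be > 0")
        if self.kind == "step" and self.level_start != self.level_end:
            raise ValueError("step segments require level_start == level_end")

    @classmethod
    def step(cls, level: float, duration: float) -> "VoltageSegment":
        return cls("step", level, level, duration)

    @classmethod
    def ramp(cls, start: float, end: float, duration: float) -> "VoltageSegment":
        return cls("ramp", start, end, duration)


@dataclass(frozen=True)
class SweepProtocol:
    """A family of sweeps sharing holding potential and sample interval.

    ``levels`` annotates the analysis-relevant potential of each sweep
    (test-step level, conditioning level, or recovery-gap duration in s for
    the recovery family).
    """

    kind: str
    holding: float
    sweeps: tuple[tuple[VoltageSegment, ...], ...]
    dt: float = 0.01  # ms
    inter_sweep_interval_s: float = 30.0
    levels: tuple[float, ...] = ()
    tail_start_index: int | None = None  # segment index of the tail, if any

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError("dt must be > 0")
        if self.levels and len(self.levels) != len(self.sweeps):
            raise ValueError("levels annotation must match the number of sweeps")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)


def _step_levels(v_min: float, v_max: float, step: float) -> np.ndarray:
    if step <= 0:
        raise ValueError("step increment must be > 0")
    if v_max <= v_min:
        raise ValueError("v_max must exceed v_min")
    n = int(round((v_max - v_min) / step)) + 1
    return v_min + step * np.arange(n)


def build_protocol(kind: str, **overrides) -> SweepProtocol:
    """Construct one of the built-in protocol families.

    Documented override keys per family:

    activation    v_min, v_max, step, test_ms, tail_ms, tail_mv, hold_ms, dt
    inactivation  v_min, v_max, step, cond_ms, test_mv, test_ms, tail_ms,
                  tail_mv, hold_ms, dt
    recovery      pre_mv, pre_ms, gaps_s (iterable), test_mv, test_ms,
                  tail_ms, hold_ms, dt
    ramp          v_start, v_end, ramp_ms, hold_ms, dt
    """
    holding = overrides.pop("holding", -100.0)
    dt = overrides.pop("dt", 0.01)
    hold_ms = overrides.pop("hold_ms", 20.0)

    def _check_unused(allowed: set[str]) -> None:
        extra = set(overrides) - allowed
        if extra:
            raise ValueError(f"unknown override(s) for {kind!r}: {sorted(extra)}")

    if kind == "activation":
        allowed = {"v_min", "v_max", "step", "test_ms", "tail_ms", "tail_mv"}
        _check_unused(allowed)
        levels = _step_levels(
            overrides.get("v_min", -100.0),
            overrides.get("v_max", 300.0),
            overrides.get("step", 20.0),
        )
        test_ms = overrides.get("test_ms", 40.0)
        tail_ms = overrides.get("tail_ms", 100.0)
        tail_mv = overrides.get("tail_mv", holding)
        sweeps = tuple(
            (
                VoltageSegment.step(holding, hold_ms),
                VoltageSegment.step(float(v), test_ms),
                VoltageSegment.step(tail_mv, tail_ms),
            )
            for v in levels
        )
        return SweepProtocol(
            kind, holding, sweeps, dt, levels=tuple(float(v) for v in levels),
            tail_start_index=2,
        )

    if kind == "inactivation":
        allowed = {"v_min", "v_max", "step", "cond_ms", "test_mv", "test_ms",
                   "tail_ms", "tail_mv"}
        _check_unused(allowed)
        levels = _step_levels(
            overrides.get("v_min", -100.0),
            overrides.get("v_max", 140.0),
            overrides.get("step", 20.0),
        )
        cond_ms = overrides.get("cond_ms", 3000.0)
        test_mv = overrides.get("test_mv", 120.0)
        test_ms = overrides.get("test_ms", 40.0)
        tail_ms = overrides.get("tail_ms", 100.0)
        tail_mv = overrides.get("tail_mv", holding)
        sweeps = tuple(
            (
                VoltageSegment.step(holding, hold_ms),
                VoltageSegment.step(float(v), cond_ms),
                VoltageSegment.step(test_mv, test_ms),
                VoltageSegment.step(tail_mv, tail_ms),
            )
            for v in levels
        )
        return SweepProtocol(
            kind, holding, sweeps, dt, levels=tuple(float(v) for v in levels),
            tail_start_index=3,
        )

    if kind == "recovery":
        allowed = {"pre_mv", "pre_ms", "gaps_s", "test_mv", "test_ms", "tail_ms"}
        _check_unused(allowed)
        pre_mv = overrides.get("pre_mv", 140.0)
        pre_ms = overrides.get("pre_ms", 1000.0)
        gaps_s = tuple(overrides.get("gaps_s", tuple(0.1 + 2.0 * k for k in range(11))))
        test_mv = overrides.get("test_mv", 140.0)
        test_ms = overrides.get("test_ms", 40.0)
        tail_ms = overrides.get("tail_ms", 100.0)
        if any(g <= 0 for g in gaps_s):
            raise ValueError("recovery gaps must be positive")
        sweeps = tuple(
            (
                VoltageSegment.step(holding, hold_ms),
                VoltageSegment.step(pre_mv, pre_ms),
                VoltageSegment.step(holding, 1000.0 * g),
                VoltageSegment.step(test_mv, test_ms),
                VoltageSegment.step(holding, tail_ms),
            )
            for g in gaps_s
        )
        return SweepProtocol(
            kind, holding, sweeps, dt, levels=tuple(float(g) for g in gaps_s),
            tail_start_index=4,
        )

    if kind == "ramp":
        allowed = {"v_start", "v_end", "ramp_ms"}
        _check_unused(allowed)
        v_start = overrides.get("v_start", -100.0)
        v_end = overrides.get("v_end", 180.0)
        ramp_ms = overrides.get("ramp_ms", 500.0)
        sweeps = (
            (
                VoltageSegment.step(holding, hold_ms),
                VoltageSegment.ramp(v_start, v_end, ramp_ms),
            ),
        )
        return SweepProtocol(kind, holding, sweeps, dt, levels=(v_end,))

    raise ValueError(
        f"unknown protocol kind {kind!r}; expected activation, inactivation, "
        "recovery or ramp"
    )
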