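"""Synthetic-data generation for every pipeline input.

No experimental recordings accompany the model, so each consumer of data is
paired with a seeded generator that produces it with the statistical
structure the analysis assumes:

* whole-cell sweeps — the kinetic model integrated over a protocol plus
  additive white Gaussian noise (pA/pF);
* single-channel ramp i–V — the piecewise-rectifying unitary current plus
  Gaussian noise (pA);
* steady-state inactivation and recovery tables — a phenomenological
  availability Boltzmann and a single-exponential recovery law.  The
  kinetic model itself deliberately has no inactivated state (inactivation
  is orders of magnitude slower than the 40-ms test pulses), so these
  datasets are generated from the phenomenological truth rather than by
  simulation.

All generators are pure functions of (model/truth, protocol, NoiseSpec).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ChannelModel, RectificationProfile
from .protocols import SweepProtocol
from .rectification import unitary_current
from .simulate import TraceSet, simulate_protocol

__all__ = [
    "NoiseSpec",
    "InactivationTruth",
    "gen_whole_cell",
    "gen_single_channel_ramp",
    "gen_inactivation_dataset",
]

#: Fixture seed used throughout the examples and tests.
DEFAULT_SEED = 20170829


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white-Gaussian noise levels and the generator seed.

    whole_cell_sd is in pA/pF (typical post-filter whole-cell baseline
    noise at desk scale), single_channel_sd in pA, tail_table_sd as a
    fraction of the maximal normalised amplitude.
    """

    whole_cell_sd: float = 0.5
    single_channel_sd: float = 0.5
    tail_table_sd: float = 0.02
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if min(self.whole_cell_sd, self.single_channel_sd, self.tail_table_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class InactivationTruth:
    """Generating truth for steady-state inactivation and recovery.

    Availability(V) = floor + (1 - floor)/(1 + exp((V - v_half)/slope_k));
    recovery(t) = 1 - (1 - start) exp(-t/recovery_tau), with the start
    level set by the availability after the conditioning potential.  The
    non-inactivating floor is not pinned down by the published curves
    (availability had not reached a plateau at +140 mV); 0.1 is a
    configurable placeholder.
    """

    v_half: float = 42.2
    slope_k: float = 20.3
    non_inactivating_floor: float = 0.1
    recovery_tau: float = 10.0  # s

    def __post_init__(self) -> None:
        if not (0.0 <= self.non_inactivating_floor < 1.0):
            raise ValueError("non_inactivating_floor must be in [0, 1)")
        if not (self.slope_k > 0 and self.recovery_tau > 0):
            raise ValueError("slope_k and recovery_tau must be > 0")

    def availability(self, v) -> np.ndarray:
        arr = np.asarray(v, dtype=float)
        f = self.non_inactivating_floor
        out = f + (1.0 - f) / (1.0 + np.exp((arr - self.v_half) / self.slope_k))
        return out if arr.ndim else float(out)


def gen_whole_cell(
    model: ChannelModel, protocol: SweepProtocol, noise: NoiseSpec = NoiseSpec()
) -> TraceSet:
    """Simulated whole-cell sweeps with additive Gaussian current noise."""
    traces = simulate_protocol(protocol, model)
    if noise.whole_cell_sd == 0:
        return traces
    rng = noise.rng()
    traces.current = [
        i + rng.normal(0.0, noise.whole_cell_sd, size=i.size) for i in traces.current
    ]
    return traces


def gen_single_channel_ramp(
    profile: RectificationProfile,
    noise: NoiseSpec = NoiseSpec(),
    *,
    v_min: float = -100.0,
    v_max: float = 180.0,
    n_points: int = 281,
) -> pd.DataFrame:
    """Single-channel ramp i–V table (columns voltage_mV, current_pA)."""
    v = np.linspace(v_min, v_max, n_points)
    i = unitary_current(v, profile)
    if noise.single_channel_sd > 0:
        i = i + noise.rng().normal(0.0, noise.single_channel_sd, size=v.size)
    return pd.DataFrame({"voltage_mV": v, "current_pA": i})


def gen_inactivation_dataset(
    truth: InactivationTruth = InactivationTruth(),
    noise: NoiseSpec = NoiseSpec(),
    *,
    conditioning_mv=None,
    recovery_t_s=None,
    conditioning_for_recovery: float = 140.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Steady-state inactivation and recovery tables from the truth model.

    Returns ``(availability_table, recovery_table)``: the first with
    columns ``conditioning_mV`` and ``normalized`` (noisy availability),
    the second with ``t_s`` and ``frac`` (noisy recovered fraction after a
    conditioning step at ``conditioning_for_recovery`` mV).
    """
    if conditioning_mv is None:
        conditioning_mv = np.arange(-100.0, 140.0 + 1e-9, 20.0)
    if recovery_t_s is None:
        recovery_t_s = 0.1 + 2.0 * np.arange(11)
    conditioning_mv = np.asarray(conditioning_mv, dtype=float)
    recovery_t_s = np.asarray(recovery_t_s, dtype=float)
    rng = noise.rng()

    avail = truth.availability(conditioning_mv)
    if noise.tail_table_sd > 0:
        avail = avail + rng.normal(0.0, noise.tail_table_sd, size=avail.size)

    start = truth.availability(conditioning_for_recovery)
    frac = 1.0 - (1.0 - start) * np.exp(-recovery_t_s / truth.recovery_tau)
    if noise.tail_table_sd > 0:
        frac = frac + rng.normal(0.0, noise.tail_table_sd, size=frac.size)

    return (
        pd.DataFrame({"conditioning_mV": conditioning_mv, "normalized": avail}),
        pd.DataFrame({"t_s": recovery_t_s, "frac": frac}),
    )
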