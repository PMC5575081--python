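"""Activation-gating kinetics: steady state, time constants, Euler integration.

The open fraction x of the channel relaxes toward its voltage-dependent
steady state x_inf(V) with time constant tau(V):

    dx/dt = (x_inf(V) - x) / tau(V)

integrated with the forward Euler method at a 0.01 ms default time step and
x(0) = 0.  For constant-voltage segments the Euler recursion has the exact
solution x_n = x_inf + (x0 - x_inf) (1 - dt/tau)^n, which is used as a fast
path; it equals the sequential iterates.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .params import ActivationParams, TimeConstantSpec

__all__ = [
    "steady_state_activation",
    "time_constant",
    "gating_step",
    "euler_constant_voltage",
    "EulerStabilityWarning",
]


class EulerStabilityWarning(UserWarning):
    """Raised when dt >= 2 tau(V), where forward Euler oscillates/diverges."""


def _check_finite_v(v) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("membrane potential must be finite")
    return arr


def steady_state_activation(v, params: ActivationParams):
    """Steady-state open fraction x_inf(V).

    x_inf = basal + amplitude / (1 + exp(-slope_inv_mv (V - V1/2)))

    Strictly increasing in V, bounded in [basal, basal + amplitude].
    Accepts scalars or arrays (vectorised); returns the matching shape.
    """
    arr = _check_finite_v(v)
    out = params.basal + params.amplitude / (
        1.0 + np.exp(-params.slope_inv_mv * (arr - params.v_half))
    )
    return out if arr.ndim else float(out)


def time_constant(v, spec: TimeConstantSpec):
    """Voltage-dependent time constant tau(V) in ms.

    Uses the depolarised branch for V >= 0 mV and the hyperpolarised branch
    for V < 0 mV; the two branches are generally discontinuous at 0 mV.
    """
    arr = _check_finite_v(v)
    if arr.ndim == 0:
        vv = float(arr)
        branch = spec.depol_branch if vv >= 0 else spec.hyperpol_branch
        return branch.tau(vv)
    out = np.empty_like(arr)
    depol = arr >= 0
    if depol.any():
        out[depol] = np.vectorize(spec.depol_branch.tau)(arr[depol])
    if (~depol).any():
        out[~depol] = np.vectorize(spec.hyperpol_branch.tau)(arr[~depol])
    return out


def gating_step(
    x: float,
    v: float,
    dt: float,
    params: ActivationParams,
    spec: TimeConstantSpec,
) -> float:
    """One forward-Euler update of the gating variable, clipped to [0, 1].

    x' = x + dt (x_inf(V) - x) / tau(V).  x = x_inf(V) is a fixed point.
    Emits :class:`EulerStabilityWarning` when dt >= 2 tau(V).
    """
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"x must be in [0, 1], got {x}")
    if not (dt > 0):
        raise ValueError(f"dt must be > 0, got {dt}")
    tau = time_constant(v, spec)
    if dt >= 2.0 * tau:
        warnings.warn(
            f"dt={dt} ms >= 2*tau={2 * tau:.4g} ms at V={v} mV: "
            "forward Euler is unstable here; result is clipped",
            EulerStabilityWarning,
            stacklevel=2,
        )
    x_inf = steady_state_activation(v, params)
    x_new = x + dt * (x_inf - x) / tau
    return min(1.0, max(0.0, x_new))


def euler_constant_voltage(
    x0: float,
    v: float,
    n_steps: int,
    dt: float,
    params: ActivationParams,
    spec: TimeConstantSpec,
) -> np.ndarray:
    """Forward-Euler trajectory over a constant-voltage segment.

    Returns the n_steps iterates x_1..x_n (x0 excluded) computed from the
    closed form of the Euler recursion.  Falls back to the clipped
    sequential update when dt >= 2 tau(V) (with a stability warning).
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    tau = time_constant(v, spec)
    x_inf = steady_state_activation(v, params)
    if dt >= 2.0 * tau:
        warnings.warn(
            f"dt={dt} ms >= 2*tau={2 * tau:.4g} ms at V={v} mV: "
            "forward Euler is unstable here; using clipped sequential updates",
            EulerStabilityWarning,
            stacklevel=2,
        )
        out = np.empty(n_steps)
        x = x0
        for k in range(n_steps):
            x = min(1.0, max(0.0, x + dt * (x_inf - x) / tau))
            out[k] = x
        return out
    a = 1.0 - dt / tau
    powers = a ** np.arange(1, n_steps + 1)
    return x_inf + (x0 - x_inf) * powers


def closed_form_relaxation(
    x0: float, v: float, t_ms, params: ActivationParams, spec: TimeConstantSpec
):
    """Exact continuous-time solution x(t) = x_inf + (x0 - x_inf) exp(-t/tau).

    Reference solution for a constant-voltage segment, used to check the
    Euler integrator's O(dt) convergence.
    """
    tau = time_constant(v, spec)
    x_inf = steady_state_activation(v, params)
    return x_inf + (x0 - x_inf) * np.exp(-np.asarray(t_ms, dtype=float) / tau)
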