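"""Measurement procedures for voltage-clamp data.

The analyses mirror standard tail-current practice for channels whose
maximal activation is only reached at extreme depolarisation:

* instantaneous tail amplitudes index the open fraction at the end of each
  test step (measured at a fixed repolarisation potential, so driving force
  and unitary conductance are common factors that cancel on normalisation);
* activation and availability curves are fitted with Boltzmann functions in
  three equivalent parameterisations (slope factor k in mV, valence z in
  elementary charges, and an offset form with free basal/amplitude);
* the gating charge is estimated independently by the limiting-slope
  method: the slope k_a of ln G against V at low open probability gives
  Z-delta = k_a * k_B T / e;
* recovery from inactivation is fitted with a single exponential.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .params import thermal_voltage_mv
from .simulate import TraceSet

__all__ = [
    "BoltzmannFitResult",
    "LimitingSlopeResult",
    "RecoveryFitResult",
    "extract_tail_amplitudes",
    "fit_boltzmann",
    "apparent_valence",
    "chord_conductance",
    "limiting_slope",
    "fit_recovery",
]

_log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Tail-current extraction


def _tail_start_sample(traces: TraceSet, sweep: int) -> int:
    idx = traces.protocol.tail_start_index
    if idx is None:
        raise ValueError("protocol has no tail segment")
    dt = traces.protocol.dt
    n = 0
    for seg in traces.protocol.sweeps[sweep][:idx]:
        n += int(round(seg.duration / dt))
    return n


def _instantaneous_amplitude(
    t: np.ndarray, i: np.ndarray, rule: str, dt: float
) -> float:
    """Amplitude of the tail at the repolarisation instant.

    ``rule="extrapolate"`` fits A exp(-t/tau) + C over the first 20 ms and
    returns A + C (the back-extrapolated value at t = 0); on fit failure it
    falls back to ``rule="window"``, the mean over 0.1–0.5 ms.
    """
    if rule == "window":
        mask = (t >= 0.1) & (t <= 0.5)
        if not mask.any():
            mask = slice(0, max(1, int(round(0.5 / dt))))
        return float(np.mean(i[mask]))
    if rule != "extrapolate":
        raise ValueError(f"unknown tail rule {rule!r}")
    mask = t <= 20.0
    tt, ii = t[mask], i[mask]
    a0 = ii[0] - ii[-1]
    c0 = ii[-1]
    tau0 = max(5.0, dt)
    try:
        popt, _ = optimize.curve_fit(
            lambda x, a, tau, c: a * np.exp(-x / tau) + c,
            tt,
            ii,
            p0=(a0, tau0, c0),
            bounds=([-np.inf, dt / 10.0, -np.inf], [np.inf, 1e4, np.inf]),
            maxfev=10000,
        )
    except RuntimeError:
        warnings.warn(
            "tail exponential fit did not converge; falling back to the "
            "0.1–0.5 ms window rule",
            stacklevel=2,
        )
        return _instantaneous_amplitude(t, i, "window", dt)
    a, _, c = popt
    return float(a + c)


def extract_tail_amplitudes(traces: TraceSet, rule: str = "extrapolate") -> pd.DataFrame:
    """Instantaneous tail amplitudes for each sweep of a TraceSet.

    Returns a table with columns ``test_mV`` (the sweep's annotated level),
    ``tail_pA_per_pF`` and ``normalized`` (amplitude divided by the value
    of largest magnitude, exactly the "normalised to the maximal peak tail
    amplitude" convention — even when the curve has not saturated).
    """
    dt = traces.protocol.dt
    amps = []
    for k in range(traces.n_sweeps):
        start = _tail_start_sample(traces, k)
        t = traces.time[k][start:] - traces.time[k][start]
        i = traces.current[k][start:]
        amps.append(_instantaneous_amplitude(t, i, rule, dt))
    amps = np.asarray(amps)
    ref = amps[int(np.argmax(np.abs(amps)))]
    levels = traces.protocol.levels or tuple(range(traces.n_sweeps))
    return pd.DataFrame(
        {
            "test_mV": np.asarray(levels, dtype=float),
            "tail_pA_per_pF": amps,
            "normalized": amps / ref,
        }
    )


# ---------------------------------------------------------------------------
# Boltzmann fitting


@dataclass
class BoltzmannFitResult:
    """A Boltzmann fit reported in all three parameterisations.

    slope_k_mv is the slope factor k (mV); slope_inv_mv = 1/k is the
    z/k_B T factor (1/mV); z = slope_inv_mv * thermal voltage is the
    apparent valence.  ``basal``/``amplitude`` are fixed at 0/1 unless the
    offset form was fitted.  ``amplitude_overshoot`` flags fits whose
    amplitude exceeds the observed span by more than 20 % (a curve that was
    not driven to saturation, as for the K452Q/K455Q mutants).
    """

    form: str
    v_half: float
    slope_k_mv: float
    slope_inv_mv: float
    z: float
    basal: float
    amplitude: float
    stderr: dict
    residual_norm: float
    converged: bool
    decreasing: bool = False
    low_confidence: bool = False
    amplitude_overshoot: bool = False


_FORMS = ("slope_k", "valence_z", "offset")


def _boltzmann_curve(form: str, decreasing: bool, kt_mv: float):
    sign = -1.0 if decreasing else 1.0

    if form == "slope_k":
        def f(v, v_half, k):
            return 1.0 / (1.0 + np.exp(-sign * (v - v_half) / k))
        return f, ("v_half", "slope_k_mv")
    if form == "valence_z":
        def f(v, v_half, z):
            return 1.0 / (1.0 + np.exp(-sign * z * (v - v_half) / kt_mv))
        return f, ("v_half", "z")

    def f(v, v_half, s, basal, amplitude):
        return basal + amplitude / (1.0 + np.exp(-sign * s * (v - v_half)))
    return f, ("v_half", "slope_inv_mv", "basal", "amplitude")


def _initial_guesses(v: np.ndarray, y: np.ndarray, decreasing: bool):
    """Neutral data-driven starting values: V1/2 from the half-range point,
    slope from the 10–90 % span (a logistic spans ln(81) ≈ 4.39 slope
    factors between those quantiles)."""
    lo, hi = float(np.min(y)), float(np.max(y))
    mid = 0.5 * (lo + hi)
    v_half0 = float(v[np.argmin(np.abs(y - mid))])
    y10 = lo + 0.1 * (hi - lo)
    y90 = lo + 0.9 * (hi - lo)
    v10 = float(v[np.argmin(np.abs(y - y10))])
    v90 = float(v[np.argmin(np.abs(y - y90))])
    span = abs(v90 - v10)
    if span == 0:
        span = max(np.ptp(v) / 4.0, 1.0)
    k0 = span / np.log(81.0)
    return v_half0, k0, lo, hi - lo


def fit_boltzmann(
    v,
    y,
    form: str = "slope_k",
    *,
    decreasing: bool = False,
    temperature: float = 298.15,
    max_restarts: int = 3,
    seed: int = 0,
) -> BoltzmannFitResult:
    """Least-squares Boltzmann fit of normalised amplitudes against voltage.

    Parameters
    ----------
    form
        "slope_k"   : y = 1/(1 + exp((V1/2 - V)/k))
        "valence_z" : y = 1/(1 + exp(-z (V - V1/2)/(k_B T/e)))
        "offset"    : y = basal + amplitude/(1 + exp(-s (V - V1/2)))
    decreasing
        Fit the mirrored (availability/inactivation) orientation; the slope
        parameter stays positive.
    """
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("v and y must be 1-D arrays of equal length")
    if form not in _FORMS:
        raise ValueError(f"form must be one of {_FORMS}, got {form!r}")
    low_confidence = v.size < 4
    if low_confidence:
        _log.warning("Boltzmann fit on %d points; flagged low-confidence", v.size)

    kt_mv = thermal_voltage_mv(temperature)
    func, names = _boltzmann_curve(form, decreasing, kt_mv)
    v_half0, k0, basal0, amp0 = _initial_guesses(v, y, decreasing)
    v_span = max(np.ptp(v), 1.0)
    if form == "slope_k":
        p0 = [v_half0, k0]
        bounds = ([v.min() - 5 * v_span, 1e-3], [v.max() + 5 * v_span, 1e4])
    elif form == "valence_z":
        p0 = [v_half0, kt_mv / k0]
        bounds = ([v.min() - 5 * v_span, 1e-4], [v.max() + 5 * v_span, 1e3])
    else:
        p0 = [v_half0, 1.0 / k0, max(basal0, 0.0), max(amp0, 1e-3)]
        bounds = (
            [v.min() - 5 * v_span, 1e-4, 0.0, 1e-6],
            [v.max() + 5 * v_span, 10.0, 1.0, 10.0],
        )

    rng = np.random.default_rng(seed)
    popt = pcov = None
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        trial = list(p0)
        if attempt:
            jitter = rng.normal(0.0, 0.1, size=len(p0))
            trial = [
                float(np.clip(p * (1.0 + j), lo + 1e-9, hi - 1e-9))
                for p, j, lo, hi in zip(trial, jitter, bounds[0], bounds[1])
            ]
        try:
            popt, pcov = optimize.curve_fit(
                func, v, y, p0=trial, bounds=bounds, maxfev=20000,
                xtol=1e-10, ftol=1e-10, gtol=1e-10,
            )
            break
        except RuntimeError as err:
            last_err = err
    if popt is None:
        raise RuntimeError(
            f"Boltzmann fit ({form}) failed after {max_restarts + 1} attempts: "
            f"{last_err}; p0={p0}, n={v.size}, y-range=({y.min():.3g}, {y.max():.3g})"
        )

    perr = np.sqrt(np.diag(pcov))
    stderr = dict(zip(names, perr))
    resid = func(v, *popt) - y
    residual_norm = float(np.linalg.norm(resid))
    converged = bool(np.all(np.isfinite(perr)))

    v_half = float(popt[0])
    if form == "slope_k":
        slope_k = float(popt[1])
        slope_inv = 1.0 / slope_k
        basal, amplitude = 0.0, 1.0
    elif form == "valence_z":
        z_fit = float(popt[1])
        slope_inv = z_fit / kt_mv
        slope_k = 1.0 / slope_inv
        basal, amplitude = 0.0, 1.0
    else:
        slope_inv = float(popt[1])
        slope_k = 1.0 / slope_inv
        basal = float(popt[2])
        amplitude = float(popt[3])
    overshoot = amplitude > 1.2 * float(np.ptp(y)) if form == "offset" else False
    if overshoot:
        _log.info(
            "fitted amplitude %.3g exceeds observed span %.3g by > 20%%: "
            "curve not saturated", amplitude, float(np.ptp(y)),
        )
    return BoltzmannFitResult(
        form=form,
        v_half=v_half,
        slope_k_mv=slope_k,
        slope_inv_mv=slope_inv,
        z=slope_inv * kt_mv,
        basal=basal,
        amplitude=amplitude,
        stderr=stderr,
        residual_norm=residual_norm,
        converged=converged,
        decreasing=decreasing,
        low_confidence=low_confidence,
        amplitude_overshoot=overshoot,
    )


def apparent_valence(slope_inv_mv: float, temperature: float = 298.15) -> float:
    """Apparent gating valence z = (z/k_B T factor) * thermal voltage.

    With the z/k_B T slope in 1/mV and the thermal voltage in mV the result
    is in elementary charges (e.g. 0.0249 * 25.69 ≈ 0.64 for WT).
    """
    if slope_inv_mv < 0:
        raise ValueError("slope_inv_mv must be >= 0")
    return slope_inv_mv * thermal_voltage_mv(temperature)


# ---------------------------------------------------------------------------
# Conductance analyses


def chord_conductance(
    voltage_mv, current, e_rev: float = 11.64, exclusion_mv: float = 2.0
):
    """Chord conductance G = I/(V - E_rev) per point.

    Points within ``exclusion_mv`` of the reversal potential are dropped
    (the quotient is numerically meaningless there); the number excluded is
    returned.  Units follow the input: pA/pF in gives nS/pF out.

    Returns ``(v_kept, g, n_excluded)``.
    """
    v = np.asarray(voltage_mv, dtype=float)
    i = np.asarray(current, dtype=float)
    if v.shape != i.shape:
        raise ValueError("voltage and current must have equal shape")
    keep = np.abs(v - e_rev) >= exclusion_mv
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError("all points fall within the reversal-potential exclusion zone")
    return v[keep], i[keep] / (v[keep] - e_rev), n_excluded


@dataclass
class LimitingSlopeResult:
    """Limiting-slope gating-charge estimate.

    k_a is the fitted slope of ln G against V (1/mV) on the selected
    window; z_delta = k_a * k_B T / e is the effective gating charge in
    elementary charges.  ``accepted`` is False when no window met the R²
    threshold (the best-slope window is still reported).
    """

    k_a: float
    z_delta: float
    window: tuple[float, float]
    r_squared: float
    n_points: int
    accepted: bool


def limiting_slope(
    conductance,
    voltage_mv,
    *,
    window_mv: float = 40.0,
    min_points: int = 4,
    r2_min: float = 0.98,
    temperature: float = 298.15,
) -> LimitingSlopeResult:
    """Limiting-slope estimate of the gating charge from a G–V relation.

    ln G is regressed on V over every sliding window at least ``window_mv``
    wide with at least ``min_points`` consecutive points; among windows with
    R² >= ``r2_min`` the one with the steepest slope is selected (the
    low-open-probability limit maximises d ln G/dV for a Boltzmann curve).
    If no window qualifies, the steepest overall is returned flagged
    ``accepted=False``.
    """
    g = np.asarray(conductance, dtype=float)
    v = np.asarray(voltage_mv, dtype=float)
    if g.shape != v.shape or g.ndim != 1:
        raise ValueError("conductance and voltage must be 1-D of equal length")
    order = np.argsort(v)
    v, g = v[order], g[order]
    if np.any(g <= 0):
        raise ValueError("conductances must be positive on the fitted range")
    ln_g = np.log(g)

    best = best_any = None
    n = v.size
    for i in range(n):
        j = i + min_points - 1
        while j < n and v[j] - v[i] < window_mv:
            j += 1
        if j >= n:
            break
        res = stats.linregress(v[i : j + 1], ln_g[i : j + 1])
        r2 = res.rvalue**2
        cand = (res.slope, r2, (float(v[i]), float(v[j])), j - i + 1)
        if best_any is None or cand[0] > best_any[0]:
            best_any = cand
        if r2 >= r2_min and (best is None or cand[0] > best[0]):
            best = cand

    if best_any is None:
        raise ValueError(
            f"not enough points for a {window_mv}-mV window with "
            f">= {min_points} points"
        )
    accepted = best is not None
    slope, r2, window, npts = best if accepted else best_any
    kt_mv = thermal_voltage_mv(temperature)
    return LimitingSlopeResult(
        k_a=float(slope),
        z_delta=float(slope * kt_mv),
        window=window,
        r_squared=float(r2),
        n_points=int(npts),
        accepted=accepted,
    )


# ---------------------------------------------------------------------------
# Recovery from inactivation


@dataclass
class RecoveryFitResult:
    """Single-exponential recovery fit frac(t) = 1 - (1 - floor) exp(-t/tau)."""

    tau_rec_s: float
    floor: float
    stderr: dict
    converged: bool
    indeterminate: bool = False


def fit_recovery(t_s, frac) -> RecoveryFitResult:
    """Fit the time course of recovery from inactivation.

    ``frac`` is the test/control current ratio after a recovery interval of
    ``t_s`` seconds; the model recovers exponentially from ``floor`` (the
    available fraction immediately after inactivation) to 1.  Data already
    at 1 everywhere yield an indeterminate (flagged) time constant.
    """
    t = np.asarray(t_s, dtype=float)
    y = np.asarray(frac, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and frac must be 1-D of equal length")
    if t.size < 4:
        raise ValueError("need at least 4 recovery durations")

    if np.ptp(y) < 1e-3 and np.all(y > 0.95):
        return RecoveryFitResult(
            tau_rec_s=float(np.min(t)),
            floor=float(np.mean(y)),
            stderr={},
            converged=True,
            indeterminate=True,
        )

    def f(x, tau, floor):
        return 1.0 - (1.0 - floor) * np.exp(-x / tau)

    tau0 = float(np.median(t))
    floor0 = float(np.clip(np.min(y), 0.0, 0.99))
    try:
        popt, pcov = optimize.curve_fit(
            f, t, y, p0=(tau0, floor0),
            bounds=([1e-6, 0.0], [1e6, 1.0]), maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"recovery fit failed: {err}; p0=({tau0}, {floor0}), n={t.size}"
        ) from err
    perr = np.sqrt(np.diag(pcov))
    return RecoveryFitResult(
        tau_rec_s=float(popt[0]),
        floor=float(popt[1]),
        stderr={"tau_rec_s": float(perr[0]), "floor": float(perr[1])},
        converged=bool(np.all(np.isfinite(perr))),
    )
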