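"""Single-channel inward rectification and the macroscopic scaling factor.

The PKD2L1 unitary conductance differs between inward and outward current
(inward-rectifying in WT and K461Q, outward-rectifying in K452Q).  Two
representations are provided:

* ``unitary_current`` — the piecewise-linear single-channel i–V with slope
  gamma_in below the limb break (upper edge of the inward fitting window)
  and gamma_out above it, zero current at the reversal potential;
* ``scaling_factor`` — the smooth multiplier SF(V) applied to the
  macroscopic maximal conductance, interpolating logistically from 1 (the
  inward limb, the normalisation reference) to gamma_out/gamma_in at
  depolarised potentials.

``fit_piecewise_conductance`` recovers the two slope conductances from an
i–V table by independent straight-line fits over the inward and outward
voltage windows, mirroring how slope conductances are read off ramp
recordings.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .params import RectificationProfile

__all__ = [
    "scaling_factor",
    "unitary_current",
    "fit_piecewise_conductance",
]


def scaling_factor(v, profile: RectificationProfile, *, form: str = "logistic"):
    """Voltage-dependent scaling factor SF(V) on the maximal conductance.

    SF interpolates between 1 at hyperpolarised potentials (inward limb,
    normalisation convention) and gamma_out/gamma_in at depolarised
    potentials.  The default form is a logistic centred at the reversal
    potential with scale ``profile.transition_width``; ``form="piecewise"``
    switches hard at the reversal potential instead.
    """
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("membrane potential must be finite")
    ratio = profile.ratio
    if form == "logistic":
        out = 1.0 + (ratio - 1.0) / (
            1.0 + np.exp(-(arr - profile.e_rev) / profile.transition_width)
        )
    elif form == "piecewise":
        out = np.where(arr < profile.e_rev, 1.0, ratio)
    else:
        raise ValueError(f"form must be 'logistic' or 'piecewise', got {form!r}")
    return out if arr.ndim else float(out)


def unitary_current(v, profile: RectificationProfile):
    """Single-channel current (pA) at potential v (mV).

    Piecewise linear: slope gamma_in (pS) below the limb break, gamma_out
    above, continuous at the break and zero at the reversal potential.
    pS * mV = fA, hence the 1e-3 factor to pA.
    """
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("membrane potential must be finite")
    vb = profile.limb_break
    i_break = profile.gamma_in * (vb - profile.e_rev)
    i_fa = np.where(
        arr <= vb,
        profile.gamma_in * (arr - profile.e_rev),
        i_break + profile.gamma_out * (arr - vb),
    )
    out = i_fa * 1e-3
    return out if arr.ndim else float(out)


def fit_piecewise_conductance(
    voltage_mv,
    current_pa,
    inward_range: tuple[float, float] = (-100.0, 40.0),
    outward_range: tuple[float, float] = (40.0, 140.0),
) -> dict:
    """Fit inward and outward slope conductances to a single-channel i–V.

    Independent least-squares straight lines over the two voltage windows;
    slopes are returned in pS (input current in pA, voltage in mV).  The
    reversal-potential estimate is the zero crossing of the inward-limb
    line.

    Returns ``{"gamma_in", "gamma_out", "e_rev_est", "stderr_in",
    "stderr_out", "n_in", "n_out"}``.
    """
    v = np.asarray(voltage_mv, dtype=float)
    i = np.asarray(current_pa, dtype=float)
    if v.shape != i.shape:
        raise ValueError("voltage and current arrays must have equal shape")

    def _limb(lo: float, hi: float, label: str):
        mask = (v >= lo) & (v <= hi)
        if mask.sum() < 3:
            raise ValueError(f"need >= 3 points in the {label} range [{lo}, {hi}] mV")
        vv, ii = v[mask], i[mask]
        if np.ptp(vv) == 0:
            raise ValueError(f"singular fit: all voltages identical in {label} range")
        res = stats.linregress(vv, ii)
        return res, int(mask.sum())

    res_in, n_in = _limb(*inward_range, "inward")
    res_out, n_out = _limb(*outward_range, "outward")
    slope_in_ps = res_in.slope * 1e3  # pA/mV -> nS -> pS
    slope_out_ps = res_out.slope * 1e3
    if res_in.slope == 0:
        e_rev_est = float("nan")
    else:
        e_rev_est = -res_in.intercept / res_in.slope
    return {
        "gamma_in": slope_in_ps,
        "gamma_out": slope_out_ps,
        "e_rev_est": e_rev_est,
        "stderr_in": res_in.stderr * 1e3,
        "stderr_out": res_out.stderr * 1e3,
        "n_in": n_in,
        "n_out": n_out,
    }
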