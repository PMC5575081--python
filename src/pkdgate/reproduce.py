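"""Self-contained recomputation of the package's benchmark quantities.

Each target regenerates its input from the shipped model parameters, runs
the relevant pipeline stage and reports the measured value, so a clean
checkout can verify the whole chain (model -> simulation -> extraction ->
fitting) without any external data.  ``reproduce`` compares the computed
values against the shipped reference table and reports pass/fail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .analysis import extract_tail_amplitudes, fit_boltzmann
from .gating import steady_state_activation
from .params import ChannelModel, builtin_model
from .protocols import build_protocol
from .simulate import simulate_protocol, steady_state_current

__all__ = ["compute_target", "compute_all", "reproduce", "TARGET_IDS"]


def _activation_curve_recovery(seed: int) -> dict:
    """Noiseless activation-curve round trip: generate normalised tail
    amplitudes from the WT whole-cell Boltzmann (V1/2 = 132.1 mV,
    k = 47.2 mV), refit from neutral guesses."""
    v = np.arange(-100.0, 300.0 + 1e-9, 20.0)
    v_half, k = 132.1, 47.2
    y = 1.0 / (1.0 + np.exp((v_half - v) / k))
    fit = fit_boltzmann(v, y, form="slope_k", seed=seed)
    return {"v_half": fit.v_half, "k": fit.slope_k_mv, "n": int(v.size)}


def _zero_crossing(model: ChannelModel) -> float:
    """Zero crossing of the steady-state simulated I–V on a 0.01-mV grid."""
    v = np.arange(-20.0, 40.0 + 1e-9, 0.01)
    i = steady_state_current(v, model)
    sign_change = np.flatnonzero(np.diff(np.signbit(i)))
    if sign_change.size == 0:
        raise RuntimeError("steady-state current has no zero crossing in [-20, 40] mV")
    j = int(sign_change[0])
    # linear interpolation between the bracketing grid points
    return float(v[j] - i[j] * (v[j + 1] - v[j]) / (i[j + 1] - i[j]))


def _pipeline_v_half(model: ChannelModel, seed: int) -> dict:
    """Full simulate -> tail-extract -> Boltzmann-fit round trip.

    Test steps are lengthened to 400 ms so every sweep reaches steady
    state; the offset Boltzmann form absorbs the basal open fraction and
    the max-tail normalisation.
    """
    protocol = build_protocol("activation", test_ms=400.0)
    traces = simulate_protocol(protocol, model)
    tails = extract_tail_amplitudes(traces)
    fit = fit_boltzmann(
        tails["test_mV"], tails["normalized"], form="offset", seed=seed
    )
    return {"v_half": fit.v_half, "n": int(protocol.n_sweeps)}


def _inactivation_recovery(seed: int) -> dict:
    """Noiseless availability round trip at the 13 conditioning potentials
    (V1/2 = 42.2 mV, k = 20.3 mV, floor 0)."""
    v = np.arange(-100.0, 140.0 + 1e-9, 20.0)
    v_half, k = 42.2, 20.3
    y = 1.0 / (1.0 + np.exp((v - v_half) / k))
    fit = fit_boltzmann(v, y, form="slope_k", decreasing=True, seed=seed)
    return {"v_half": fit.v_half, "n": int(v.size)}


def compute_target(target_id: str, *, seed: int = 0, model: ChannelModel | None = None) -> dict:
    """Compute one benchmark quantity from scratch.

    Returns ``{"value": float, "n": int}``.  ``model`` overrides the WT
    bundle for the targets that use it (t5, t6, t7); unknown ids raise.
    """
    wt = model or builtin_model("WT")
    if target_id == "t1":
        r = _activation_curve_recovery(seed)
        return {"value": r["v_half"], "n": r["n"]}
    if target_id == "t2":
        r = _activation_curve_recovery(seed)
        return {"value": r["k"], "n": r["n"]}
    if target_id == "t5":
        return {"value": _zero_crossing(wt), "n": 6001}
    if target_id == "t6":
        return {"value": float(steady_state_activation(-1000.0, wt.activation)), "n": 1}
    if target_id == "t7":
        r = _pipeline_v_half(wt, seed)
        return {"value": r["v_half"], "n": r["n"]}
    if target_id == "t8":
        r = _pipeline_v_half(builtin_model("K461Q"), seed)
        return {"value": r["v_half"], "n": r["n"]}
    if target_id == "t9":
        r = _inactivation_recovery(seed)
        return {"value": r["v_half"], "n": r["n"]}
    raise ValueError(f"unknown target id {target_id!r}")


def _reference_table() -> dict:
    text = resources.files("pkdgate").joinpath("data/reference_targets.json").read_text()
    return json.loads(text)


TARGET_IDS = ("t1", "t2", "t5", "t6", "t7", "t8", "t9")


def compute_all(seed: int = 0) -> dict[str, dict]:
    """Compute every benchmark target; see :func:`compute_target`."""
    return {tid: compute_target(tid, seed=seed) for tid in TARGET_IDS}


def reproduce(
    targets_path: str | Path | None = None,
    out_path: str | Path | None = None,
    *,
    seed: int = 0,
    model: ChannelModel | None = None,
) -> dict:
    """Run the reproduction harness and compare against reference values.

    ``targets_path`` may point to a JSON list of target ids or of objects
    with an ``id`` field; None runs all shipped targets.  Returns a report
    ``{"passed": bool, "targets": {id: {value, expected, tol, ok, n}}}``
    and writes it to ``out_path`` if given.
    """
    reference = _reference_table()
    if targets_path is None:
        ids = list(TARGET_IDS)
    else:
        raw = json.loads(Path(targets_path).read_text())
        ids = [t if isinstance(t, str) else t["id"] for t in raw]
    report: dict = {"passed": True, "seed": seed, "targets": {}}
    for tid in ids:
        if tid not in reference:
            raise ValueError(f"unknown target id {tid!r}")
        ref = reference[tid]
        res = compute_target(tid, seed=seed, model=model)
        ok = abs(res["value"] - ref["expected"]) <= ref["tol"]
        report["targets"][tid] = {
            "value": res["value"],
            "expected": ref["expected"],
            "tol": ref["tol"],
            "units": ref.get("units", ""),
            "n": res["n"],
            "ok": ok,
        }
        report["passed"] = report["passed"] and ok
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2) + "\n")
    return report
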