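"""Gating-charge estimation by the limiting-slope method.

Builds the steady-state chord conductance of the WT model, regresses ln G
on V over sliding low-open-probability windows and converts the steepest
well-fitting slope k_a to a charge Z-delta = k_a kT/e.  Run twice: once on
the offset-free Boltzmann (recovers the full apparent valence) and once on
the model conductance including its 0.02 constitutive basal fraction, which
flattens ln G at negative potentials and lowers the apparent charge.
"""

import numpy as np

from pkdgate import (
    apparent_valence,
    builtin_model,
    limiting_slope,
    steady_state_activation,
)

wt = builtin_model("WT")
v = np.arange(-200.0, 300.0 + 1e-9, 10.0)

pure = 1.0 / (1.0 + np.exp(-wt.activation.slope_inv_mv * (v - wt.activation.v_half)))
res_pure = limiting_slope(pure, v)

with_basal = steady_state_activation(v, wt.activation)
res_basal = limiting_slope(with_basal, v)

z_app = apparent_valence(wt.activation.slope_inv_mv)
print(f"apparent valence from Boltzmann slope : {z_app:.3f} e0")
print(
    f"limiting slope, offset-free Boltzmann  : {res_pure.z_delta:.3f} e0 "
    f"(window {res_pure.window} mV, R^2={res_pure.r_squared:.4f})"
)
print(
    f"limiting slope, with 0.02 basal open   : {res_basal.z_delta:.3f} e0 "
    f"(window {res_basal.window} mV)"
)

# The limiting slope equals the full valence (~0.64) only when conductance
# vanishes at negative potentials; the channel's constitutive activity caps
# the steepness of ln G, so the measurable apparent charge drops to ~0.48 —
# the same ordering seen between Z_app and the experimentally estimated
# gate charge.
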