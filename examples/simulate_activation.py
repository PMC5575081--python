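"""Simulate WT whole-cell currents under the step-activation protocol.

Holds the cell at -100 mV, applies 40-ms test steps from -100 to +300 mV in
20-mV increments, and integrates the gating model (forward Euler, 0.01 ms)
with the rectification scaling factor applied to the maximal conductance.
"""

import numpy as np

from pkdgate import build_protocol, builtin_model, simulate_protocol

model = builtin_model("WT")
protocol = build_protocol("activation")
traces = simulate_protocol(protocol, model)

print("sweep  step(mV)  I_end(pA/pF)  x_end")
n_end = int(round(60.0 / protocol.dt)) - 1  # last sample of the test pulse
for k, level in enumerate(protocol.levels):
    print(
        f"{k:5d}  {level:8.0f}  {traces.current[k][n_end]:12.2f}"
        f"  {traces.x[k][n_end]:.4f}"
    )

# I_end is the current density at the end of each test step: outward above
# the 11.64 mV reversal potential and saturating as the open fraction x_end
# approaches its maximum (~0.98) at strong depolarisation.
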