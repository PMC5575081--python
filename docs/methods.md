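# Methods

## Model

Macroscopic PKD2L1 current density (pA/pF) is modelled as

    I(t) = G_max · SF(V) · x(t) · (V − E_rev),      E_rev = 11.64 mV,

with a single activation variable x obeying the first-order relaxation

    dx/dt = (x_inf(V) − x) / τ(V),

integrated by forward Euler with dt = 0.01 ms and x = 0 at the start of
every sweep.  The model is restricted to activation/deactivation gating:
inactivation develops over seconds and recovers over tens of seconds, so
within the ≤ 400-ms pulses simulated here it is negligible and is handled
separately (see "Synthetic data").

**Steady-state activation.**  x_inf(V) = basal + amplitude/(1 + exp(−s(V −
V½))) with basal = 0.02 and amplitude = 0.98 for every variant; only V½ and
the slope s = z/k_B T differ per channel (WT 138.3 mV / 0.0249 mV⁻¹, K452Q
295.0 / 0.0234, K455Q 280.0 / 0.0233, K461Q 182.7 / 0.0217).  The basal
term is the channel's constitutive activity; whether mutants share the WT
floor is not established, so it is a per-channel override with the WT
value as default.

**Time constants.**  τ(V) uses a logistic family for V ≥ 0 and an
exponential family for V < 0.  The two branches are discontinuous at V = 0
(WT: 20.16 ms from the right vs 10.9 ms from the left); they are
implemented exactly as published, branch chosen by sign, with no smoothing
— fidelity over cosmetics.  The published K452Q depolarised expression,
60.6/(1 + exp(0.008 V − 70)), is numerically a constant 60.6 ms because the
exponent is ≈ −70 over the physiological range; it is kept literal by
default, with `k452q_tau_interpretation="parenthesised"` switching to
60.6/(1 + exp(0.008 (V − 70))) for users who read it as a typo.  No
simulated K452Q time-course value exists to disambiguate the two.

**Rectification.**  The unitary (single-channel) i–V is piecewise linear:
slope γ_in below the limb break at +40 mV (the upper edge of the inward
fitting window), γ_out above it, continuous at the break and zero at
E_rev.  Table values (pS, inward/outward): WT 161.9/102.4, K452Q
117.3/137.8 (outward-rectifying — the code never assumes γ_out/γ_in < 1),
K455Q 125.5/77.0, K461Q 184.3/85.9.  The macroscopic scaling factor SF(V)
has no published closed form (only plotted curves), so it is modelled as a
logistic between 1 (inward limb, the normalisation reference) and
γ_out/γ_in, centred at E_rev with a 15-mV transition width; width, centre
and a hard piecewise alternative are configurable.  SF multiplies the
whole conductance, basal component included.

**Constants.**  Temperature defaults to 298.15 K (recordings at room
temperature, 22–27 °C); the thermal voltage k_B T/e = 25.69 mV is always
recomputed from it.  G_max (nS/pF) is not identifiable from normalised
tail analysis and defaults to 1; every fit in the package is invariant to
it.

## Numerics

Step-voltage segments use the exact solution of the Euler recursion,
x_n = x_inf + (x0 − x_inf)(1 − dt/τ)ⁿ, which equals the sequential iterates
algebraically and is deterministic; ramp segments update sample by sample
against the instantaneous command voltage.  x is clipped to [0, 1] after
each update — unreachable at the default step, relevant only in the
dt ≥ 2τ regime, where a stability warning is emitted and the sequential
clipped update is used.  The Euler error against the exponential solution
is first order in dt (halving dt halves the max error); at dt = 0.01 ms it
is below 10⁻³ wherever τ ≥ 2 ms, and grows to ≈ 4·10⁻³ of the relaxation
amplitude at +300 mV where τ_WT ≈ 0.42 ms — irrelevant to steady-state
measurements but stated here as the bound.  Segment durations that are not
multiples of dt are rounded to the nearest sample with a logged warning.

## Measurement procedures

**Tail extraction.**  The "instantaneous" tail amplitude is obtained by
fitting A·exp(−t/τ) + C to the first 20 ms after repolarisation and
back-extrapolating to the repolarisation instant (unbiased under the
model's single-exponential deactivation); a mean over 0.1–0.5 ms
post-repolarisation is available as the alternative rule and is the
automatic fallback if the fit fails.  Amplitudes are normalised to the
value of largest magnitude even when the curve has not saturated;
offset-form fits whose amplitude exceeds the observed span by > 20 % are
flagged (the K452Q/K455Q situation).

**Boltzmann fits.**  Bounded nonlinear least squares (scipy trust-region)
with data-driven initial guesses — V½ from the half-range point, slope
from the 10–90 % span (ln 81 ≈ 4.39 slope factors) — and up to three
seeded, jittered restarts on non-convergence; tolerances 10⁻¹⁰.  Three
parameterisations are reported consistently: slope factor k (mV), the
z/k_B T factor 1/k, and valence z = k_B T/(e·k).  Fits on fewer than four
points are flagged low-confidence.  Availability (inactivation) curves use
the mirrored orientation with k kept positive.

**Limiting slope.**  "Marginal conductance range" has no published
operational definition, so the default rule is reproducible and logged:
regress ln G on V over every sliding window of ≥ 4 consecutive points
spanning ≥ 40 mV, accept windows with R² ≥ 0.98, and take the steepest —
for a Boltzmann conductance the slope is maximal in the low-open-probability
limit, so the rule lands there automatically.  If no window passes R², the
steepest is returned flagged unaccepted.  Zδ = k_a·k_B T/e.  On an
offset-free Boltzmann with the WT slope this returns 0.64 e₀ (± 0.01 on a
10-mV grid reaching −200 mV); on the WT model conductance the 0.02 basal
fraction flattens ln G at negative potentials and caps the estimate at
≈ 0.48 e₀ — the analytic maximum of d ln G/dV·k_B T/e for these parameters
— reproducing the qualitative ordering Zδ < Z_app seen experimentally.

**Chord conductance.**  G = I/(V − E_rev); points within 2 mV of E_rev are
excluded (count reported) since the quotient degenerates there.

**Recovery.**  frac(t) = 1 − (1 − floor)·exp(−t/τ_rec), fitted by bounded
least squares; data already at 1 everywhere are flagged indeterminate
rather than fitted.

## Synthetic data

The generators produce every input the pipeline consumes, as pure
functions of (model/truth, protocol, NoiseSpec):

* **Whole-cell sweeps** — the kinetic model over a protocol plus additive
  white Gaussian noise (default SD 0.5 pA/pF, a typical post-filter
  baseline at desk scale).
* **Single-channel ramp i–V** — the piecewise unitary current over a
  −100…+180 mV grid plus Gaussian noise (default SD 0.5 pA).
* **Inactivation/recovery tables** — generated phenomenologically, not by
  adding an inactivated state to the model: availability(V) = floor +
  (1 − floor)/(1 + exp((V − V½)/k)) with V½ = 42.2 mV, k = 20.3 mV, and
  recovery(t) = 1 − (1 − start)·exp(−t/τ_rec) with τ_rec = 10 s, the start
  level being the availability after the conditioning potential.  The
  non-inactivating floor is not pinned down by the data (availability had
  not plateaued at +140 mV); 0.1 is an explicit, configurable placeholder.
  τ_rec = 10 s sits in the observed "tens of seconds" regime and keeps
  recovery > 100× slower than activation (τ ≈ 11 ms at +140 mV).

What the generators do **not** emulate: capacitance transients, seal leak,
series-resistance error, 1/f or flicker noise, stochastic single-channel
gating, and run-to-run variability of gating parameters.  Passing tests
therefore demonstrate estimator correctness and pipeline self-consistency
under the model's own assumptions — not robustness to those artefacts in
real recordings.

The fixture seed is 20170829.

## Protocols and problem sizes

Built-in protocols: activation (hold −100 mV, 40-ms steps −100…+300 mV in
20-mV increments, 21 sweeps; +400 mV extension gives 26; 100-ms tail at
−100 mV — long enough for the ≈ 12-ms WT deactivation), steady-state
inactivation (3-s conditioning −100…+140 mV, 13 levels, 40-ms test at
+120 mV; the 40-ms figure-protocol duration is the default, the 50-ms
variant mentioned elsewhere is an override), recovery (1-s conditioning at
+140 mV, gap at the −100 mV holding potential — the biologically sensible
reading of an ambiguous published description — of 0.1–20.1 s, 40-ms test
at +140 mV), and a −100→+180 mV ramp.  The 30-s inter-sweep interval is
annotation only, since the model holds no inactivation state.  Parameter-
recovery benchmarks lengthen the activation test pulses to 400 ms so every
variant reaches steady state (≥ 6 time constants even for the 60.6-ms
K452Q τ); with dt = 0.01 ms that is ~5·10⁴ samples per sweep and the full
21-sweep pipeline runs in well under a second.

## Known limitations

* Single activation gate: no Markov multi-state scheme, no gating-current
  (Q–V) prediction, no Q10 temperature scaling.
* SF(V)'s logistic form and 15-mV width are a modelling choice constrained
  only by the two conductance limits; the true voltage dependence between
  the limbs is not identified.
* The τ branches' discontinuity at 0 mV is inherited from the published
  piecewise fits; trajectories crossing 0 mV slowly will show a small
  kink in dx/dt there.
* Loading traces from CSV reconstructs step protocols only; ramps are not
  inferred from sampled voltages.
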