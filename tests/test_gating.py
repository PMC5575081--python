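"""Steady-state activation, time constants and the Euler gating update."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkdgate import (
    ActivationParams,
    ChannelType,
    EulerStabilityWarning,
    builtin_model,
    gating_step,
    steady_state_activation,
    time_constant,
)
from pkdgate.gating import closed_form_relaxation, euler_constant_voltage


class TestSteadyStateActivation:
    @pytest.mark.parametrize(
        "v, expected, tol",
        [
            (138.3, 0.51, 1e-12),       # midpoint: basal + amplitude/2
            (-1000.0, 0.02, 1e-6),      # hyperpolarised limit = basal
            (300.0, 0.9828, 1e-4),      # direct evaluation of the WT Boltzmann
        ],
    )
    def test_wt_reference_points(self, wt, v, expected, tol):
        assert steady_state_activation(v, wt.activation) == pytest.approx(
            expected, abs=tol
        )

    def test_bounded_between_basal_and_basal_plus_amplitude(self, each_model):
        p = each_model.activation
        v = np.linspace(-500, 500, 2001)
        x = steady_state_activation(v, p)
        assert np.all(x >= p.basal - 1e-12)
        assert np.all(x <= p.basal + p.amplitude + 1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        v1=st.floats(-500, 500),
        dv=st.floats(1e-6, 100),
        label=st.sampled_from(list(ChannelType)),
    )
    def test_strictly_increasing_in_v(self, v1, dv, label):
        p = builtin_model(label).activation
        assert steady_state_activation(v1 + dv, p) > steady_state_activation(v1, p)

    def test_nonfinite_potential_rejected(self, wt):
        with pytest.raises(ValueError):
            steady_state_activation(float("nan"), wt.activation)
        with pytest.raises(ValueError):
            steady_state_activation(float("inf"), wt.activation)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"v_half": 0.0, "slope_inv_mv": -1.0},
            {"v_half": 0.0, "slope_inv_mv": 0.02, "basal": 1.5},
            {"v_half": 0.0, "slope_inv_mv": 0.02, "basal": 0.5, "amplitude": 0.6},
            {"v_half": 0.0, "slope_inv_mv": 0.02, "amplitude": -0.1},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ActivationParams(**kwargs)


class TestTimeConstant:
    @pytest.mark.parametrize(
        "channel, v, expected, tol",
        [
            ("WT", 145.0, 10.35, 1e-12),       # logistic midpoint 20.7/2
            ("K461Q", 125.2, 5.06, 1e-12),     # logistic midpoint 10.12/2
            ("WT", -100.0, 12.046, 1e-3),      # 10.9 exp(0.1)
        ],
    )
    def test_reference_points(self, channel, v, expected, tol):
        spec = builtin_model(channel).tau
        assert time_constant(v, spec) == pytest.approx(expected, abs=tol)

    def test_positive_over_wide_voltage_range(self, each_model):
        v = np.linspace(-200, 500, 1401)
        tau = time_constant(v, each_model.tau)
        assert np.all(tau > 0)

    def test_branch_switch_at_zero(self, wt):
        # the published branches are discontinuous at V = 0 (by design)
        left = time_constant(-1e-9, wt.tau)
        right = time_constant(0.0, wt.tau)
        assert left == pytest.approx(10.9, abs=1e-6)
        assert right == pytest.approx(20.7 / (1 + math.exp(0.025 * -145)), rel=1e-9)
        assert abs(left - right) > 5.0

    def test_k452q_literal_is_near_constant_parenthesised_is_not(self):
        lit = builtin_model("K452Q").tau
        par = builtin_model("K452Q", k452q_tau_interpretation="parenthesised").tau
        v = np.linspace(0, 300, 31)
        tau_lit = time_constant(v, lit)
        tau_par = time_constant(v, par)
        assert np.ptp(tau_lit) < 1e-6  # exp(0.008 V - 70) is ~0 everywhere
        assert np.ptp(tau_par) > 10.0
        assert time_constant(70.0, par) == pytest.approx(60.6 / 2)

    def test_unknown_channel_label_rejected(self):
        with pytest.raises(ValueError, match="unknown channel"):
            builtin_model("R455Q")


class TestGatingStep:
    def test_fixed_point_at_steady_state(self, each_model):
        for v in (-80.0, 0.0, 150.0):
            x_inf = steady_state_activation(v, each_model.activation)
            x_new = gating_step(x_inf, v, 0.01, each_model.activation, each_model.tau)
            assert x_new == pytest.approx(x_inf, abs=1e-15)

    def test_single_step_from_zero(self, wt):
        # dt/tau(145) * x_inf(145) = 0.01/10.35 * 0.55078
        x = gating_step(0.0, 145.0, 0.01, wt.activation, wt.tau)
        assert x == pytest.approx(5.32e-4, abs=1e-6)

    def test_multi_step_matches_exponential_relaxation(self, wt):
        v, dt, n = 145.0, 0.01, 5000
        x = 0.0
        for _ in range(n):
            x = gating_step(x, v, dt, wt.activation, wt.tau)
        tau = time_constant(v, wt.tau)
        x_inf = steady_state_activation(v, wt.activation)
        expected = x_inf * (1 - math.exp(-n * dt / tau))
        assert x == pytest.approx(expected, abs=dt / tau)

    def test_stability_warning_when_dt_exceeds_two_tau(self, wt):
        tau = time_constant(145.0, wt.tau)
        with pytest.warns(EulerStabilityWarning):
            x = gating_step(0.5, 145.0, 2.5 * tau, wt.activation, wt.tau)
        assert 0.0 <= x <= 1.0  # clipped, not an error

    def test_invalid_inputs_rejected(self, wt):
        with pytest.raises(ValueError):
            gating_step(1.5, 0.0, 0.01, wt.activation, wt.tau)
        with pytest.raises(ValueError):
            gating_step(0.5, 0.0, -0.01, wt.activation, wt.tau)


class TestEulerIntegration:
    def test_matches_sequential_updates(self, wt):
        v, dt, n = 120.0, 0.01, 200
        fast = euler_constant_voltage(0.0, v, n, dt, wt.activation, wt.tau)
        x = 0.0
        seq = []
        for _ in range(n):
            x = gating_step(x, v, dt, wt.activation, wt.tau)
            seq.append(x)
        np.testing.assert_allclose(fast, seq, rtol=1e-10)

    def test_accuracy_against_closed_form_at_default_step(self, each_model):
        # where dt/tau <= 5e-3 the Euler trajectory tracks the exponential
        # relaxation to better than 1e-3 over 100 ms
        dt = 0.01
        for v in (-100.0, -40.0, 0.0, 60.0, 120.0):
            tau = time_constant(v, each_model.tau)
            if dt / tau > 5e-3:
                continue
            n = int(round(100.0 / dt))
            x_euler = euler_constant_voltage(
                0.0, v, n, dt, each_model.activation, each_model.tau
            )
            t = dt * np.arange(1, n + 1)
            x_exact = closed_form_relaxation(
                0.0, v, t, each_model.activation, each_model.tau
            )
            assert np.max(np.abs(x_euler - x_exact)) < 1e-3

    def test_halving_dt_at_least_halves_max_error(self, wt):
        v, total = 145.0, 100.0

        def max_err(dt):
            n = int(round(total / dt))
            x = euler_constant_voltage(0.0, v, n, dt, wt.activation, wt.tau)
            t = dt * np.arange(1, n + 1)
            return np.max(np.abs(x - closed_form_relaxation(0.0, v, t, wt.activation, wt.tau)))

        e1, e2, e4 = max_err(0.04), max_err(0.02), max_err(0.01)
        assert e2 <= e1 / 2 * 1.05
        assert e4 <= e2 / 2 * 1.05


def test_shipped_valence_ordering():
    """The z/kBT slopes of the shipped parameter sets order WT > K452Q > K455Q > K461Q."""
    slopes = [
        builtin_model(c).activation.slope_inv_mv
        for c in ("WT", "K452Q", "K455Q", "K461Q")
    ]
    assert slopes == sorted(slopes, reverse=True)
    assert slopes == [0.0249, 0.0234, 0.0233, 0.0217]
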