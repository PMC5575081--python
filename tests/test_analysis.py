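"""Tail extraction, Boltzmann fitting, conductance and recovery analyses."""

import numpy as np
import pytest

from pkdgate import (
    apparent_valence,
    build_protocol,
    builtin_model,
    chord_conductance,
    extract_tail_amplitudes,
    fit_boltzmann,
    fit_recovery,
    limiting_slope,
    scaling_factor,
    simulate_protocol,
    steady_state_activation,
    steady_state_current,
    thermal_voltage_mv,
    time_constant,
)


@pytest.fixture(scope="module")
def wt_traces():
    wt = builtin_model("WT")
    return simulate_protocol(build_protocol("activation", test_ms=400.0), wt), wt


class TestTailExtraction:
    def test_amplitude_matches_analytic_value(self, wt_traces):
        traces, wt = wt_traces
        tails = extract_tail_amplitudes(traces)
        k = list(traces.protocol.levels).index(300.0)
        x_end = steady_state_activation(300.0, wt.activation)
        expected = (
            wt.constants.g_max
            * scaling_factor(-100.0, wt.rectification)
            * x_end
            * (-100.0 - wt.constants.e_rev)
        )
        assert tails["tail_pA_per_pF"][k] == pytest.approx(expected, rel=5e-3)

    def test_amplitudes_increase_in_magnitude_with_test_potential(self, wt_traces):
        traces, _ = wt_traces
        tails = extract_tail_amplitudes(traces)
        mags = np.abs(tails["tail_pA_per_pF"].to_numpy())
        assert np.all(np.diff(mags) > 0)

    def test_normalisation_to_maximal_amplitude(self, wt_traces):
        traces, _ = wt_traces
        tails = extract_tail_amplitudes(traces)
        assert tails["normalized"].max() == pytest.approx(1.0)
        assert np.all(tails["normalized"] > 0)

    def test_window_rule_agrees_with_extrapolation_on_clean_data(self, wt_traces):
        traces, _ = wt_traces
        a = extract_tail_amplitudes(traces, rule="extrapolate")
        b = extract_tail_amplitudes(traces, rule="window")
        # x barely decays within 0.5 ms of repolarisation (tau ~12 ms)
        np.testing.assert_allclose(
            a["tail_pA_per_pF"], b["tail_pA_per_pF"], rtol=0.05
        )

    def test_test_step_at_holding_gives_basal_tail(self, wt_traces):
        traces, wt = wt_traces
        tails = extract_tail_amplitudes(traces)
        k = list(traces.protocol.levels).index(-100.0)
        # no added activation: the tail reflects only basal/holding gating
        x_hold = steady_state_activation(-100.0, wt.activation)
        bound = (
            wt.constants.g_max
            * scaling_factor(-100.0, wt.rectification)
            * x_hold
            * abs(-100.0 - wt.constants.e_rev)
        )
        assert abs(tails["tail_pA_per_pF"][k]) <= bound * 1.05


class TestBoltzmannFit:
    def test_recovers_whole_cell_activation_parameters(self):
        v = np.arange(-100.0, 300.0 + 1e-9, 20.0)
        y = 1.0 / (1.0 + np.exp((132.1 - v) / 47.2))
        fit = fit_boltzmann(v, y, form="slope_k")
        assert fit.v_half == pytest.approx(132.1, abs=0.1)
        assert fit.slope_k_mv == pytest.approx(47.2, abs=0.1)
        assert fit.converged

    def test_symmetric_points_give_zero_midpoint(self):
        v = np.array([-50.0, 0.0, 50.0])
        y = np.array([0.25, 0.5, 0.75])
        fit = fit_boltzmann(v, y, form="slope_k")
        assert fit.v_half == pytest.approx(0.0, abs=1e-6)
        assert fit.low_confidence  # only 3 points

    def test_recovers_inactivation_parameters(self):
        v = np.arange(-100.0, 140.0 + 1e-9, 20.0)
        y = 1.0 / (1.0 + np.exp((v - 42.2) / 20.3))
        fit = fit_boltzmann(v, y, form="slope_k", decreasing=True)
        assert fit.v_half == pytest.approx(42.2, abs=0.1)
        assert fit.slope_k_mv == pytest.approx(20.3, abs=0.1)

    def test_parameterisations_are_consistent(self):
        v = np.arange(-100.0, 300.0 + 1e-9, 20.0)
        y = 1.0 / (1.0 + np.exp((132.1 - v) / 47.2))
        kt = thermal_voltage_mv(298.15)
        fit_k = fit_boltzmann(v, y, form="slope_k")
        fit_z = fit_boltzmann(v, y, form="valence_z")
        assert fit_z.z == pytest.approx(kt / fit_k.slope_k_mv, rel=1e-6)
        assert fit_k.z == pytest.approx(fit_z.z, rel=1e-6)

    def test_offset_form_flags_unsaturated_curve(self):
        # half-activation far beyond the sampled range (K452Q-like)
        v = np.arange(-100.0, 300.0 + 1e-9, 20.0)
        m = builtin_model("K452Q").activation
        y = steady_state_activation(v, m)
        y = y / y.max()
        fit = fit_boltzmann(v, y, form="offset")
        assert fit.v_half == pytest.approx(m.v_half, abs=1.0)
        assert fit.amplitude_overshoot

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fit_boltzmann([0.0, 1.0], [0.5])


class TestApparentValence:
    @pytest.mark.parametrize(
        "slope, expected",
        [(0.0249, 0.64), (0.0217, 0.56), (0.0, 0.0)],
    )
    def test_reference_values(self, slope, expected):
        assert apparent_valence(slope, 298.15) == pytest.approx(expected, abs=0.005)

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            apparent_valence(-0.01)


class TestChordConductance:
    def test_arithmetic(self):
        v, g, n_exc = chord_conductance([111.64], [100.0], e_rev=11.64)
        assert g[0] == pytest.approx(1.0)
        assert n_exc == 0

    def test_points_near_reversal_excluded(self):
        v_in = np.array([10.64, 11.64, 12.64, 100.0])
        v, g, n_exc = chord_conductance(v_in, np.ones(4), e_rev=11.64)
        assert n_exc == 3
        assert list(v) == [100.0]

    def test_all_points_excluded_raises(self):
        with pytest.raises(ValueError):
            chord_conductance([11.0, 12.0], [1.0, 1.0], e_rev=11.64)

    def test_model_identity_on_steady_state_sweeps(self, wt):
        v = np.arange(-100.0, 300.0 + 1e-9, 20.0)
        i = steady_state_current(v, wt)
        vk, g, _ = chord_conductance(v, i, e_rev=wt.constants.e_rev)
        expected = (
            wt.constants.g_max
            * scaling_factor(vk, wt.rectification)
            * steady_state_activation(vk, wt.activation)
        )
        np.testing.assert_allclose(g, expected, rtol=1e-3)


class TestLimitingSlope:
    def test_pure_boltzmann_recovers_valence(self):
        v = np.arange(-200.0, 300.0 + 1e-9, 10.0)
        g = 1.0 / (1.0 + np.exp(-0.0249 * (v - 138.3)))
        res = limiting_slope(g, v)
        assert res.accepted
        assert res.z_delta == pytest.approx(apparent_valence(0.0249), abs=0.01)

    def test_flat_conductance_gives_zero_charge(self):
        v = np.arange(-100.0, 100.0 + 1e-9, 10.0)
        res = limiting_slope(np.ones_like(v), v)
        assert res.z_delta == pytest.approx(0.0, abs=1e-12)

    def test_basal_offset_lowers_apparent_charge(self, wt):
        v = np.arange(-200.0, 300.0 + 1e-9, 10.0)
        g = steady_state_activation(v, wt.activation)  # includes 0.02 basal
        res = limiting_slope(g, v)
        z_app = apparent_valence(wt.activation.slope_inv_mv)
        assert res.z_delta < z_app
        # brute-force window scan as an independent check of the maximum
        kt = thermal_voltage_mv(298.15)
        best = max(
            np.polyfit(v[i : i + 5], np.log(g[i : i + 5]), 1)[0]
            for i in range(v.size - 4)
        )
        assert res.z_delta == pytest.approx(best * kt, rel=1e-6)

    def test_invariant_to_conductance_scaling(self):
        v = np.arange(-200.0, 300.0 + 1e-9, 10.0)
        g = 1.0 / (1.0 + np.exp(-0.0249 * (v - 138.3)))
        a = limiting_slope(g, v)
        b = limiting_slope(1e3 * g, v)
        assert a.z_delta == pytest.approx(b.z_delta, rel=1e-12)
        assert a.window == b.window

    def test_nonpositive_conductance_rejected(self):
        v = np.arange(0.0, 100.0, 10.0)
        with pytest.raises(ValueError):
            limiting_slope(np.linspace(-1, 1, v.size), v)


class TestRecoveryFit:
    def test_recovers_generating_time_constant(self):
        t = 0.1 + 2.0 * np.arange(11)
        frac = 1.0 - (1.0 - 0.107) * np.exp(-t / 10.0)
        res = fit_recovery(t, frac)
        assert res.tau_rec_s == pytest.approx(10.0, abs=0.1)
        assert res.floor == pytest.approx(0.107, abs=0.01)
        assert not res.indeterminate

    def test_fully_recovered_data_flagged_indeterminate(self):
        t = np.array([0.1, 1.0, 5.0, 10.0, 20.0])
        res = fit_recovery(t, np.full(5, 0.9999))
        assert res.indeterminate

    def test_recovery_far_slower_than_activation(self, wt):
        t = 0.1 + 2.0 * np.arange(11)
        frac = 1.0 - 0.9 * np.exp(-t / 10.0)
        res = fit_recovery(t, frac)
        tau_act_ms = time_constant(140.0, wt.tau)
        assert res.tau_rec_s * 1000.0 > 100.0 * tau_act_ms

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_recovery([1.0, 2.0, 3.0], [0.5, 0.7, 0.8])
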