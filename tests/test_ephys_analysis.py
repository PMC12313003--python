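"""Passive membrane properties, STC/K⁺ decay fitting, dialysis assay."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gliaphys import ephys as ea
from gliaphys.datatypes import Sweep
from gliaphys.synth import (
    EphysGroundTruth,
    coupling_for_depolarization,
    simulate_iv_sweeps,
    simulate_na_dialysis_vm,
    simulate_stc_sweeps,
)


class TestIVAndResistance:
    def test_ideal_ohmic_recovery(self, default_ephys_gt):
        sweeps = simulate_iv_sweeps(default_ephys_gt, noise=False)
        iv = ea.steady_state_iv(sweeps)
        r_m = ea.membrane_resistance(iv, default_ephys_gt.r_pipette)
        assert r_m == pytest.approx(25.0, abs=1e-9)

    def test_zero_pipette_returns_total_resistance(self, default_ephys_gt):
        sweeps = simulate_iv_sweeps(default_ephys_gt, noise=False)
        iv = ea.steady_state_iv(sweeps)
        assert ea.membrane_resistance(iv, 0.0) == pytest.approx(30.0)

    def test_noisy_recovery_within_half_mohm(self, default_ephys_gt):
        sweeps = simulate_iv_sweeps(default_ephys_gt, noise=True, seed=2)
        iv = ea.steady_state_iv(sweeps)
        r_m = ea.membrane_resistance(iv, default_ephys_gt.r_pipette)
        assert r_m == pytest.approx(25.0, abs=0.5)

    def test_intercept_sits_at_rest_potential(self, default_ephys_gt):
        from scipy.stats import linregress

        sweeps = simulate_iv_sweeps(default_ephys_gt, noise=False)
        iv = ea.steady_state_iv(sweeps)
        fit = linregress(iv.step_voltages, iv.steady_state_currents)
        v_zero_current = -fit.intercept / fit.slope
        assert v_zero_current == pytest.approx(default_ephys_gt.v_rest)

    def test_estimator_invariant_to_rest_potential(self):
        a = simulate_iv_sweeps(EphysGroundTruth(v_rest=-80.0), noise=False)
        b = simulate_iv_sweeps(EphysGroundTruth(v_rest=-60.0), noise=False)
        r_a = ea.membrane_resistance(ea.steady_state_iv(a), 5.0)
        r_b = ea.membrane_resistance(ea.steady_state_iv(b), 5.0)
        assert r_a == pytest.approx(r_b)

    def test_nonlinear_iv_flagged(self):
        """A saturating (non-ohmic) I–V, e.g. from a window catching a
        transient, triggers the linearity warning."""
        volts = np.arange(-120.0, 31.0, 10.0)
        sweeps = []
        for v in volts:
            i_sat = 2000.0 * np.tanh((v + 80.0) / 40.0)
            sweeps.append(
                Sweep(
                    samples=np.full(1000, i_sat), sampling_rate=1000.0,
                    protocol_tag="iv_step",
                    meta={"step_voltage": v, "step_start": 0.0,
                          "step_duration": 1.0},
                )
            )
        from gliaphys.datatypes import SweepSet

        with pytest.warns(UserWarning, match="linearity"):
            ea.steady_state_iv(SweepSet(sweeps=sweeps, protocol="iv"))


class TestRestingPotential:
    def test_constant_trace(self):
        sweep = Sweep(
            samples=np.full(5000, -81.8), sampling_rate=5000.0,
            protocol_tag="vm_monitor", kind="voltage",
        )
        assert ea.resting_potential(sweep) == pytest.approx(-81.8)

    def test_uses_early_window_not_global_mean(self):
        samples = np.concatenate([np.full(1000, -80.0), np.full(9000, -40.0)])
        sweep = Sweep(
            samples=samples, sampling_rate=1000.0,
            protocol_tag="vm_monitor", kind="voltage",
        )
        assert ea.resting_potential(sweep, window=1.0) == pytest.approx(-80.0)

    def test_current_sweep_rejected(self):
        sweep = Sweep(samples=np.zeros(10), sampling_rate=1.0,
                      protocol_tag="x", kind="current")
        with pytest.raises(ValueError):
            ea.resting_potential(sweep)


class TestAveraging:
    def test_identical_repeats_unchanged(self, default_ephys_gt):
        sweeps = simulate_stc_sweeps(default_ephys_gt, n_pulses=1, noise=False)
        avg = ea.average_repeats(sweeps)
        np.testing.assert_allclose(
            avg.samples, sweeps.sweeps[0].samples, rtol=1e-12, atol=1e-12
        )

    def test_missing_repeat_warns_but_proceeds(self, default_ephys_gt):
        sweeps = simulate_stc_sweeps(default_ephys_gt, n_pulses=1, repeats=4)
        with pytest.warns(UserWarning, match="expected 5"):
            avg = ea.average_repeats(sweeps)
        assert avg.meta["n_averaged"] == 4

    def test_length_mismatch_rejected(self):
        a = Sweep(samples=np.zeros(10), sampling_rate=1.0, protocol_tag="x")
        b = Sweep(samples=np.zeros(11), sampling_rate=1.0, protocol_tag="x")
        with pytest.raises(ValueError):
            ea.average_repeats([a, b], expected=2)


class TestTrainSubtraction:
    def test_identical_traces_give_zero(self):
        s = Sweep(samples=np.sin(np.linspace(0, 1, 100)), sampling_rate=100.0,
                  protocol_tag="stc_train10", meta={"stim_time": 0.1})
        diff = ea.isolate_10th_pulse_stc(s, s)
        np.testing.assert_allclose(diff.samples, 0.0, atol=1e-12)

    @settings(max_examples=25, derandomize=True)
    @given(offset=st.floats(min_value=-50.0, max_value=50.0))
    def test_subtraction_linearity(self, offset):
        """isolate(a+c, b+c) == isolate(a, b) for any common component c."""
        rng = np.random.default_rng(0)
        a = rng.normal(size=500)
        b = rng.normal(size=500)
        c = offset * np.sin(np.linspace(0, 3, 500))

        def wrap(x):
            return Sweep(samples=x, sampling_rate=1000.0,
                         protocol_tag="t", meta={"stim_time": 0.1})

        d1 = ea.isolate_10th_pulse_stc(wrap(a + c), wrap(b + c))
        d2 = ea.isolate_10th_pulse_stc(wrap(a), wrap(b))
        np.testing.assert_allclose(d1.samples, d2.samples, atol=1e-9)

    def test_mismatched_sampling_rejected(self):
        a = Sweep(samples=np.zeros(10), sampling_rate=1.0, protocol_tag="x")
        b = Sweep(samples=np.zeros(10), sampling_rate=2.0, protocol_tag="x")
        with pytest.raises(ValueError):
            ea.isolate_10th_pulse_stc(a, b)

    def test_isolated_trace_decays_with_fast_tau_not_k_tau(self, default_ephys_gt):
        gt = default_ephys_gt
        t9 = ea.average_repeats(
            simulate_stc_sweeps(gt, n_pulses=9, noise=False), expected=5
        )
        t10 = ea.average_repeats(
            simulate_stc_sweeps(gt, n_pulses=10, noise=False), expected=5
        )
        iso = ea.isolate_10th_pulse_stc(t10, t9)
        fit = ea.stc_decay_time(iso)
        expected_ms = gt.stc_tau * gt.tau_scale[9] * 1e3
        assert fit.tau_ms == pytest.approx(expected_ms, rel=1e-4)
        assert fit.tau < 0.1 * gt.k_tau


class TestMonoExponentialFit:
    def test_noiseless_model_class_exact(self):
        tau = 7.353e-3
        fs = 10_000.0
        t = np.arange(int(0.2 * fs)) / fs
        trace = -120.0 * np.exp(-t / tau) + 3.0
        fit = ea.fit_monoexponential_decay(trace, fs, (0.0, 0.1))
        assert fit.tau == pytest.approx(tau, rel=1e-6)
        assert fit.amplitude == pytest.approx(-120.0, rel=1e-6)
        assert fit.offset == pytest.approx(3.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_trace_flagged_unidentifiable(self):
        fit = ea.fit_monoexponential_decay(np.zeros(100), 1000.0, (0.0, 0.1))
        assert not fit.identifiable
        assert fit.amplitude == 0.0

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            ea.fit_monoexponential_decay(np.zeros(10), 10.0, (0.0, 5.0))

    def test_noisy_tau_recovery_within_2pct(self):
        """Monte-Carlo: mean fitted τ over 50 noisy replicates within 2%."""
        tau = 8.951e-3
        fs = 10_000.0
        t = np.arange(int(0.3 * fs)) / fs
        rng = np.random.default_rng(0)
        taus = []
        for _ in range(50):
            trace = -120.0 * np.exp(-t / tau) + rng.normal(0, 2.0, t.size)
            taus.append(ea.fit_monoexponential_decay(trace, fs, (0.0, 0.1)).tau)
        assert np.mean(taus) == pytest.approx(tau, rel=0.02)


class TestSTCDecayTime:
    def test_noiseless_single_pulse_recovery(self, default_ephys_gt):
        gt = default_ephys_gt
        sweeps = simulate_stc_sweeps(gt, n_pulses=1, noise=False, include_k=False)
        fit = ea.stc_decay_time(ea.average_repeats(sweeps))
        assert fit.tau_ms == pytest.approx(7.353, rel=1e-4)

    def test_slow_component_contamination_below_5pct(self, default_ephys_gt):
        sweeps = simulate_stc_sweeps(default_ephys_gt, n_pulses=1, noise=False)
        fit = ea.stc_decay_time(ea.average_repeats(sweeps))
        assert fit.tau_ms == pytest.approx(7.353, rel=0.05)

    def test_window_on_slow_tail_returns_k_tau(self, default_ephys_gt):
        """Window sensitivity: fitting long after the stimulus captures the
        slow K⁺ decay instead of the fast STC (documented behavior)."""
        gt = default_ephys_gt
        sweeps = simulate_stc_sweeps(gt, n_pulses=1, noise=False)
        avg = ea.average_repeats(sweeps)
        fit = ea.fit_monoexponential_decay(
            avg.samples, gt.sampling_rate, (0.4, 0.8)
        )
        assert fit.tau == pytest.approx(gt.k_tau, rel=0.05)

    def test_monte_carlo_recovery_within_5pct(self, default_ephys_gt):
        gt = default_ephys_gt
        taus = [
            ea.stc_decay_time(
                ea.average_repeats(simulate_stc_sweeps(gt, n_pulses=1, seed=i))
            ).tau_ms
            for i in range(30)
        ]
        assert np.mean(taus) == pytest.approx(7.353, rel=0.05)


class TestKCurrentDecay:
    def test_noiseless_recovery(self, default_ephys_gt):
        gt = default_ephys_gt
        avg = ea.average_repeats(
            simulate_stc_sweeps(gt, n_pulses=10, noise=False), expected=5
        )
        fit = ea.k_current_decay_time(avg)
        assert fit.tau == pytest.approx(1.856, rel=1e-4)

    def test_monte_carlo_recovery_within_5pct(self):
        gt = EphysGroundTruth(k_tau=1.844)
        taus = [
            ea.k_current_decay_time(
                ea.average_repeats(simulate_stc_sweeps(gt, n_pulses=10, seed=i))
            ).tau
            for i in range(20)
        ]
        assert np.mean(taus) == pytest.approx(1.844, rel=0.05)

    def test_zero_amplitude_unidentifiable(self, default_ephys_gt):
        gt = EphysGroundTruth(k_increment=0.0)
        avg = ea.average_repeats(
            simulate_stc_sweeps(gt, n_pulses=10, noise=False), expected=5
        )
        fit = ea.k_current_decay_time(avg)
        assert not fit.identifiable


class TestSaturationRatioAndDialysis:
    @pytest.mark.parametrize(
        "tau10, tau1, expected",
        [(12.12, 7.353, 1.648), (15.53, 8.951, 1.735), (5.0, 5.0, 1.0)],
    )
    def test_saturation_ratio(self, tau10, tau1, expected):
        assert ea.saturation_ratio(tau10, tau1) == pytest.approx(expected, abs=5e-4)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            ea.saturation_ratio(10.0, 0.0)

    def test_constant_trace_gives_zero_depolarization(self):
        sweep = Sweep(samples=np.full(7000, -80.0), sampling_rate=10.0,
                      protocol_tag="vm_monitor", kind="voltage")
        assert ea.dialysis_depolarization(sweep) == pytest.approx(0.0)

    def test_uncoupled_cell_depolarizes_by_rest_magnitude(self):
        gt = EphysGroundTruth(coupling_strength=0.0, v_rest=-50.0)
        vm = simulate_na_dialysis_vm(gt, noise=False)
        dvm = ea.dialysis_depolarization(vm)
        assert dvm == pytest.approx(50.0, abs=3.0)

    def test_tuned_coupling_recovered_within_noise(self):
        c = coupling_for_depolarization(6.5, v_rest=-81.83)
        gt = EphysGroundTruth(coupling_strength=c, v_rest=-81.83)
        vm = simulate_na_dialysis_vm(gt, noise=True, seed=4)
        assert ea.dialysis_depolarization(vm) == pytest.approx(6.5, abs=0.5)

    def test_short_series_rejected(self):
        sweep = Sweep(samples=np.zeros(100), sampling_rate=10.0,
                      protocol_tag="vm_monitor", kind="voltage")
        with pytest.raises(ValueError):
            ea.dialysis_depolarization(sweep, t_measure=600.0)
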