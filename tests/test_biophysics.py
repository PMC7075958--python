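"""Parameter recovery for the voltage-clamp analysis equations."""

import numpy as np
import pytest

from mhf import (
    StepRecording,
    boltzmann,
    conductance_curve,
    fit_activation_tau,
    fit_boltzmann,
    leak_subtract,
    synthesize_step_recording,
    vsp_decay,
)
from mhf.errors import FitError, ProtocolError

VOLTAGES = np.arange(-100.0, 21.0, 10.0)  # 13 steps, as in a standard protocol


class TestLeakSubtract:
    def test_control_equal_to_recording_zeroes_everything(self):
        rec = synthesize_step_recording(noise_sd_pA=0.0)
        out = leak_subtract(rec, rec)
        assert np.allclose(out.currents, 0.0)

    def test_zero_control_is_identity(self):
        rec = synthesize_step_recording()
        zero = StepRecording(
            voltages=rec.voltages,
            time_ms=rec.time_ms,
            currents=np.zeros_like(rec.currents),
        )
        out = leak_subtract(rec, zero)
        assert np.allclose(out.currents, rec.currents)

    def test_recovers_signal_from_known_decomposition(self):
        signal = synthesize_step_recording(leak_conductance_nS=0.0)
        leaky = synthesize_step_recording(leak_conductance_nS=1.5)
        control = StepRecording(
            voltages=signal.voltages,
            time_ms=signal.time_ms,
            currents=leaky.currents - signal.currents,
        )
        out = leak_subtract(leaky, control)
        assert np.allclose(out.currents, signal.currents, atol=1e-9)

    def test_protocol_mismatch_rejected(self):
        rec = synthesize_step_recording(voltages=[-60, -40, -20])
        ctl = synthesize_step_recording(voltages=[-60, -40, 0])
        with pytest.raises(ProtocolError):
            leak_subtract(rec, ctl)


class TestConductanceCurve:
    def test_ohmic_current_gives_flat_unit_conductance(self):
        v = np.array([-60.0, -40.0, -20.0, 0.0, 20.0])
        t = np.arange(0.0, 100.0, 1.0)
        currents = np.outer(2.0 * (v + 80.0), np.ones_like(t))
        rec = StepRecording(voltages=v, time_ms=t, currents=currents)
        volts, g = conductance_curve(rec, reversal_potential_mV=-80.0)
        assert np.allclose(g, 1.0)

    def test_gated_currents_recover_generating_sigmoid(self):
        rec = synthesize_step_recording(
            voltages=VOLTAGES, v_half=-25.0, k=9.0, tau_ms=50.0,
            duration_ms=1500.0,
        )
        volts, g = conductance_curve(rec)
        po = boltzmann(volts, -25.0, 9.0)
        assert np.allclose(g, po / po.max(), atol=1e-6)
        assert g.max() == pytest.approx(1.0)
        assert ((g >= 0) & (g <= 1)).all()

    def test_step_at_reversal_excluded_with_warning(self):
        v = np.array([-80.0, -40.0, 0.0, 20.0])
        t = np.arange(0.0, 10.0, 1.0)
        currents = np.outer(1.0 * (v + 80.0), np.ones_like(t))
        rec = StepRecording(voltages=v, time_ms=t, currents=currents)
        with pytest.warns(UserWarning, match="reversal"):
            volts, g = conductance_curve(rec, reversal_potential_mV=-80.0)
        assert -80.0 not in volts


class TestFitBoltzmann:
    def test_noiseless_identifiability(self):
        g = boltzmann(VOLTAGES, -25.0, 9.0)
        fit = fit_boltzmann(VOLTAGES, g)
        assert abs(fit.v_half - (-25.0)) < 0.1
        assert abs(fit.k - 9.0) < 0.1
        assert fit.residual_norm < 1e-8

    def test_fitted_curve_is_half_at_v_half(self):
        g = boltzmann(VOLTAGES, -30.0, 7.0)
        fit = fit_boltzmann(VOLTAGES, g)
        assert fit.predict(np.array([fit.v_half]))[0] == pytest.approx(0.5)

    def test_noisy_recovery_median_error_below_one_mv(self):
        rng = np.random.default_rng(1)
        errors = []
        for _ in range(50):
            g = boltzmann(VOLTAGES, -25.0, 9.0) + rng.normal(0, 0.03, VOLTAGES.size)
            fit = fit_boltzmann(VOLTAGES, g)
            errors.append(abs(fit.v_half - (-25.0)))
        assert np.median(errors) < 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_boltzmann([-30, -20, -10], [0.2, 0.5, 0.8])


class TestFitActivationTau:
    def test_noiseless_recovery(self):
        t = np.arange(0.0, 1500.0, 2.0)
        trace = 800.0 * (1 - np.exp(-t / 120.0)) + 15.0
        tau = fit_activation_tau(t, trace)
        assert abs(tau - 120.0) < 1.0

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(2)
        t = np.arange(0.0, 1500.0, 2.0)
        clean = 800.0 * (1 - np.exp(-t / 120.0))
        errs = []
        for _ in range(20):
            tau = fit_activation_tau(t, clean + rng.normal(0, 40.0, t.size))
            errs.append(abs(tau - 120.0) / 120.0)
        assert np.median(errs) < 0.10

    def test_flat_trace_is_an_error(self):
        t = np.arange(0.0, 100.0, 1.0)
        with pytest.raises(FitError):
            fit_activation_tau(t, np.full_like(t, 5.0))


class TestVspDecay:
    @staticmethod
    def decay_recording(tau_s=4.0, plateau=0.3, peak=500.0):
        t = np.arange(0.0, 10_001.0, 10.0)
        trace = peak * (plateau + (1 - plateau) * np.exp(-t / (tau_s * 1000.0)))
        return StepRecording(
            voltages=np.array([60.0]), time_ms=t, currents=trace[None, :]
        ), t

    def test_constant_current_means_no_decay(self):
        t = np.arange(0.0, 10_001.0, 10.0)
        rec = StepRecording(
            voltages=np.array([40.0]),
            time_ms=t,
            currents=np.full((1, t.size), 250.0),
        )
        res = vsp_decay(rec)
        assert res.ratio[0] == pytest.approx(1.0)
        assert res.decay_percent[0] == pytest.approx(0.0)

    def test_exponential_decay_matches_closed_form(self):
        rec, t = self.decay_recording(tau_s=4.0, plateau=0.3)
        res = vsp_decay(rec)
        expected = 0.3 + 0.7 * np.exp(-10.0 / 4.0)
        assert res.ratio[0] == pytest.approx(expected, abs=1e-9)

    def test_ratio_invariant_to_current_scaling(self):
        rec, _ = self.decay_recording(peak=500.0)
        scaled = StepRecording(
            voltages=rec.voltages, time_ms=rec.time_ms, currents=rec.currents * 3.7
        )
        assert vsp_decay(scaled).ratio[0] == pytest.approx(vsp_decay(rec).ratio[0])

    def test_nonpositive_peak_is_an_error(self):
        t = np.arange(0.0, 10_001.0, 10.0)
        rec = StepRecording(
            voltages=np.array([40.0]), time_ms=t, currents=np.full((1, t.size), -5.0)
        )
        with pytest.raises(FitError):
            vsp_decay(rec)

    def test_short_trace_rejected(self):
        t = np.arange(0.0, 500.0, 10.0)
        rec = StepRecording(
            voltages=np.array([40.0]), time_ms=t, currents=np.full((1, t.size), 5.0)
        )
        with pytest.raises(ProtocolError):
            vsp_decay(rec)
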