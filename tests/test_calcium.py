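"""Calibration, decay fitting and submembrane reconstruction oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiosk.calcium import (CalibrationError, CalibrationParams, NoDecayError,
                              SubmembraneParams, calibrate_fluorescence,
                              fit_single_exponential, inverse_calibrate,
                              reconstruct_submembrane, submembrane_forward)
from cardiosk.io_model import TimeSeries


def ts(values, dt=1.0, unit="a.u."):
    return TimeSeries(0.0, dt, np.asarray(values, float), unit)


class TestCalibration:
    def test_lower_anchor_f_equals_fmin(self, calibration):
        ca = calibrate_fluorescence(ts([calibration.fmin] * 10), calibration)
        assert np.allclose(ca.values, 0.0)

    def test_direct_evaluation_midscale(self, calibration):
        # F = 0.5 with Fmax 1, Fmin 1/15: Kd * (0.5 - 1/15) / 0.5
        ca = calibrate_fluorescence(ts([0.5, 0.5]), calibration)
        expected = 1.58 * (0.5 - 1.0 / 15.0) / 0.5
        assert np.allclose(ca.values, expected, rtol=1e-12)
        assert np.isclose(expected, 1.3693333333333333)

    def test_at_or_above_fmax_raises_with_index(self, calibration):
        with pytest.raises(CalibrationError, match="index 3"):
            calibrate_fluorescence(ts([0.5, 0.5, 0.5, 1.0]), calibration)

    def test_below_fmin_clips_to_zero(self, calibration):
        ca = calibrate_fluorescence(ts([0.01, 0.5]), calibration)
        assert ca.values[0] == 0.0 and ca.values[1] > 0

    def test_inverse_anchors(self, calibration):
        f = inverse_calibrate(ts([0.0, 0.0], unit="uM"), calibration)
        assert np.allclose(f.values, calibration.fmin)
        f = inverse_calibrate(ts([calibration.kd] * 2, unit="uM"), calibration)
        assert np.allclose(f.values, (calibration.fmax + calibration.fmin) / 2)
        f = inverse_calibrate(ts([1e6, 1e6], unit="uM"), calibration)
        assert np.allclose(f.values, calibration.fmax, rtol=1e-4)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1e3), min_size=2, max_size=30))
    def test_round_trip_property(self, ca_values):
        p = CalibrationParams(fmax=1000.0)
        ca = ts(ca_values, unit="uM")
        back = calibrate_fluorescence(inverse_calibrate(ca, p), p)
        assert np.allclose(back.values, ca.values, rtol=1e-9, atol=1e-9)


class TestExpDecayFit:
    def test_exact_recovery_noiseless(self):
        t = np.arange(0.0, 1000.0, 2.0)
        y = 0.1 + 1.0 * np.exp(-t / 220.0)
        fit = fit_single_exponential(ts(y, dt=2.0), t_start=0.0)
        assert np.isclose(fit.amplitude, 1.0, rtol=1e-6)
        assert np.isclose(fit.tau, 220.0, rtol=1e-6)
        assert np.isclose(fit.baseline, 0.1, rtol=1e-6)
        assert fit.rmse < 1e-9

    def test_constant_trace_rejected(self):
        with pytest.raises(NoDecayError):
            fit_single_exponential(ts(np.full(100, 0.5)), t_start=0.0)

    def test_too_few_samples_rejected(self):
        y = np.exp(-np.arange(8.0) / 3.0)
        with pytest.raises(ValueError, match="10 samples"):
            fit_single_exponential(ts(y), t_start=0.0)

    def test_tau_recovery_under_noise(self):
        # 2% additive noise: median tau error over 50 seeds within 5%
        t = np.arange(0.0, 1000.0, 2.0)
        clean = 0.1 + 1.0 * np.exp(-t / 220.0)
        taus = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            noisy = clean + rng.normal(0.0, 0.02, clean.size)
            taus.append(fit_single_exponential(ts(noisy, dt=2.0), 0.0).tau)
        assert abs(np.median(taus) / 220.0 - 1.0) < 0.05


class TestSubmembrane:
    def test_constant_input_passes_through(self):
        out = reconstruct_submembrane(ts(np.full(100, 0.1), unit="uM"))
        assert np.allclose(out.ca_sm.values, 0.1)
        assert out.decay_fit is None

    def test_exponential_closed_form(self):
        # ca_i = A exp(-t/tau): forward estimate A (1 - gamma/tau) exp(-t/tau)
        dt, tau, gamma, A = 0.5, 220.0, 110.0, 1.0
        t = np.arange(0.0, 600.0, dt)
        ca = A * np.exp(-t / tau)
        raw = submembrane_forward(ts(ca, dt=dt, unit="uM"), SubmembraneParams())
        expected = A * (1.0 - gamma / tau) * np.exp(-t / tau)
        interior = slice(5, -5)
        assert np.allclose(raw.values[interior], expected[interior], rtol=1e-6)

    def test_linear_ramp_offset_is_gamma_times_slope(self):
        m = 0.01  # uM/ms
        t = np.arange(0.0, 200.0, 1.0)
        raw = submembrane_forward(ts(0.2 + m * t, unit="uM"), SubmembraneParams())
        interior = slice(3, -3)
        assert np.allclose((raw.values - (0.2 + m * t))[interior], 110.0 * m,
                           rtol=1e-9)

    def test_savitzky_golay_polynomial_exactness(self):
        # quadratic input is invariant under the order-2 smoother (interior)
        t = np.arange(0.0, 50.0, 1.0)
        y = 0.3 + 0.02 * t + 0.001 * t**2
        p = SubmembraneParams()
        raw = submembrane_forward(ts(y, unit="uM"), p)
        deriv_expected = 0.02 + 0.002 * t
        interior = slice(3, -3)
        assert np.allclose(raw.values[interior],
                           (y + 110.0 * deriv_expected)[interior], rtol=1e-9)

    def test_unimodal_transient_leads_bulk(self):
        # reconstruction peaks earlier and at least as high as the bulk signal
        t = np.arange(0.0, 800.0, 5.0)
        rel = np.clip(t - 50.0, 0.0, None)
        ca = 0.1 + 0.8 * (1 - np.exp(-rel / 15.0)) ** 2 * np.exp(-rel / 200.0)
        ca[t < 50.0] = 0.1
        out = reconstruct_submembrane(ts(ca, dt=5.0, unit="uM"))
        assert out.ca_sm.values.max() >= ca.max()
        assert np.argmax(out.ca_sm.values) <= np.argmax(ca)

    def test_decay_tail_follows_bulk_tau(self):
        t = np.arange(0.0, 1500.0, 5.0)
        rel = np.clip(t - 50.0, 0.0, None)
        ca = 0.1 + 0.8 * (1 - np.exp(-rel / 15.0)) ** 2 * np.exp(-rel / 200.0)
        ca[t < 50.0] = 0.1
        out = reconstruct_submembrane(ts(ca, dt=5.0, unit="uM"))
        assert out.decay_fit is not None
        assert np.isclose(out.decay_fit.tau, 200.0, rtol=0.05)
        # late tail: log-slope of (ca_sm - baseline) matches -1/tau
        sl = slice(150, 250)
        resid = out.ca_sm.values[sl] - out.decay_fit.baseline
        slope = np.polyfit(t[sl], np.log(resid), 1)[0]
        assert np.isclose(-1.0 / slope, out.decay_fit.tau, rtol=1e-3)

    def test_strictly_rising_input_has_no_decay(self):
        t = np.arange(0.0, 100.0, 1.0)
        with pytest.raises(NoDecayError):
            reconstruct_submembrane(ts(0.1 + 0.01 * t, unit="uM"))
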