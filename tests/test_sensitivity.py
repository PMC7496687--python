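"""Ramp extraction, Hill fitting and biphasic timing metrics."""

from dataclasses import replace

import numpy as np
import pytest

from cardiosk.io_model import TimeSeries
from cardiosk.sensitivity import (RampError, RampPairs, extract_ramp,
                                  fit_hill, fit_inhibition, timing_metrics)
from cardiosk.simulate import GatingParams, open_probability


def hill(ca, ec50, h):
    return 1.0 / (1.0 + (ec50 / ca) ** h)


def _decay_ramp(ec50=0.46, h=2.6, ca0=2.0, tau=200.0, n=120, dt=5.0, imax=500.0):
    """I_SK proportional to Hill(ca) along an exponential ca decay."""
    t = dt * np.arange(n)
    ca = 0.05 + (ca0 - 0.05) * np.exp(-t / tau)
    isk = imax * hill(ca, ec50, h)
    return (TimeSeries(0.0, dt, isk, "pA"), TimeSeries(0.0, dt, ca, "uM"), imax)


class TestExtractRamp:
    def test_pairs_lie_on_the_hill_curve(self):
        isk, ca, imax = _decay_ramp()
        pairs = extract_ramp(isk, ca, imax)
        assert np.allclose(pairs.i_norm, hill(pairs.ca, 0.46, 2.6), rtol=1e-12)

    def test_self_imax_first_point_is_one(self):
        isk, ca, _ = _decay_ramp()
        pairs = extract_ramp(isk, ca, float(isk.values.max()))
        assert np.isclose(pairs.i_norm[0], 1.0)

    def test_rising_ca_is_degenerate(self):
        t = np.arange(50.0)
        ca = TimeSeries(0.0, 1.0, 0.1 + 0.01 * t, "uM")
        isk = TimeSeries(0.0, 1.0, np.concatenate([[5.0], np.full(49, 1.0)]), "pA")
        with pytest.raises(RampError, match="never decreases"):
            extract_ramp(isk, ca, 5.0)

    def test_peak_at_end_is_degenerate(self):
        t = np.arange(50.0)
        isk = TimeSeries(0.0, 1.0, t, "pA")
        ca = TimeSeries(0.0, 1.0, 2.0 - 0.01 * t, "uM")
        with pytest.raises(RampError, match="trace end"):
            extract_ramp(isk, ca, 50.0)

    def test_non_monotone_jitter_is_dropped_not_smoothed(self):
        isk, ca, imax = _decay_ramp()
        vals = ca.values.copy()
        vals[10] = vals[9] + 0.5  # a single upward glitch
        pairs = extract_ramp(isk, ca.with_values(vals), imax)
        assert np.all(np.diff(pairs.ca) < 0)
        assert 10 not in (pairs.t / ca.dt).astype(int)


class TestFitHill:
    @pytest.mark.parametrize("ec50,h", [
        (0.2, 1.5), (0.46, 2.6), (1.0, 4.0), (0.23, 2.5), (0.46, 1.0),
    ])
    def test_noiseless_recovery_is_exact(self, ec50, h):
        isk, ca, imax = _decay_ramp(ec50=ec50, h=h, ca0=max(2.0, 6 * ec50))
        fit = fit_hill(extract_ramp(isk, ca, imax))
        assert np.isclose(fit.ec50, ec50, rtol=1e-6)
        assert np.isclose(fit.h, h, rtol=1e-6)
        assert fit.reliable

    def test_noisy_recovery_median_within_5_percent(self):
        # 2% additive current noise, 100 seeds
        ec, hs = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            isk, ca, imax = _decay_ramp()
            noisy = isk.with_values(isk.values + rng.normal(0, 0.02 * imax,
                                                            isk.values.size))
            try:
                fit = fit_hill(extract_ramp(noisy, ca, imax))
            except RampError:
                continue
            ec.append(fit.ec50)
            hs.append(fit.h)
        assert abs(np.median(ec) / 0.46 - 1) < 0.05
        assert abs(np.median(hs) / 2.6 - 1) < 0.05

    def test_scale_equivariance(self):
        isk, ca, imax = _decay_ramp()
        f1 = fit_hill(extract_ramp(isk, ca, imax))
        f2 = fit_hill(extract_ramp(isk.with_values(isk.values * 3.7), ca,
                                   imax * 3.7))
        assert np.isclose(f1.ec50, f2.ec50, rtol=1e-9)
        assert np.isclose(f1.h, f2.h, rtol=1e-9)

    def test_insufficient_span_rejected(self):
        isk, ca, imax = _decay_ramp(ca0=0.2, n=20)  # shallow decay
        with pytest.raises(RampError, match="fold"):
            fit_hill(extract_ramp(isk, ca, imax))


class TestFitInhibition:
    @pytest.mark.parametrize("ic50_ref", [10.0, 20.0, 40.0])
    def test_descending_limb_recovers_ic50(self, ic50_ref):
        g = GatingParams(ic50_ref=ic50_ref)
        ca = np.geomspace(3.0, 300.0, 40)  # well above the activation range
        po = open_probability(ca, -40.0, g)
        fit = fit_inhibition(ca, po)
        assert np.isclose(fit.ic50, ic50_ref, rtol=0.02)
        assert np.isclose(fit.h, g.h_inh, rtol=0.05)


class TestTiming:
    def _bump(self, peak_t, dt=1.0, n=300, width=40.0):
        t = dt * np.arange(n)
        return TimeSeries(0.0, dt, np.exp(-((t - peak_t) / width) ** 2), "pA")

    def test_identical_traces_have_identical_metrics(self):
        isk = self._bump(120.0)
        ca = isk.with_values(isk.values, unit="uM")
        tm = timing_metrics(isk, ca, 20.0)
        assert tm.ttp_isk == tm.ttp_casm
        assert tm.ca_sm_at_peak_isk == tm.ca_sm_peak

    def test_onset_shift_translates_both(self):
        isk = self._bump(120.0)
        ca = self._bump(160.0).with_values(self._bump(160.0).values, unit="uM")
        t1 = timing_metrics(isk, ca, 20.0)
        t2 = timing_metrics(isk, ca, 25.0)
        assert np.isclose(t1.ttp_isk - t2.ttp_isk, 5.0)
        assert np.isclose(t1.ttp_casm - t2.ttp_casm, 5.0)

    def test_onset_outside_span_rejected(self):
        isk = self._bump(50.0, n=100)
        ca = isk.with_values(isk.values, unit="uM")
        with pytest.raises(ValueError, match="onset"):
            timing_metrics(isk, ca, 500.0)

    def test_biphasic_current_peaks_before_submembrane_calcium(self, no_noise):
        # simulator sweep at -10 mV, default (baseline) gating
        from cardiosk.simulate import preset, simulate_sweep
        from cardiosk.io_model import StepProtocol
        b = preset("tab-baseline")
        protocol = StepProtocol(-40.0, -10.0, 50.0, 300.0)
        sw = simulate_sweep(protocol, b["transient"], b["gating"], b["ica"],
                            no_noise, with_sk=True)
        isk = TimeSeries(0.0, 0.2, sw.truth.i_sk, "pA")
        ca_sm = TimeSeries(0.0, 0.2, sw.truth.ca_sm, "uM")
        tm = timing_metrics(isk, ca_sm, 50.0)
        assert tm.ttp_isk < tm.ttp_casm
        assert tm.ca_sm_at_peak_isk < tm.ca_sm_peak

    def test_inhibition_midpoint_governs_calcium_at_peak_current(self, no_noise):
        # raising IC50_ref moves the I_SK peak to higher [Ca2+]_sm (10x range)
        from cardiosk.simulate import preset, simulate_sweep
        from cardiosk.io_model import StepProtocol
        b = preset("tab-baseline")
        protocol = StepProtocol(-40.0, -10.0, 50.0, 300.0)
        values = []
        for scale in (0.5, 1.0, 2.0, 5.0):
            g = replace(b["gating"], ic50_ref=20.0 * scale)
            sw = simulate_sweep(protocol, b["transient"], g, b["ica"],
                                no_noise, with_sk=True)
            tm = timing_metrics(TimeSeries(0.0, 0.2, sw.truth.i_sk, "pA"),
                                TimeSeries(0.0, 0.2, sw.truth.ca_sm, "uM"), 50.0)
            values.append(tm.ca_sm_at_peak_isk)
        assert np.all(np.diff(values) > 0)


def test_ramp_pairs_validation():
    with pytest.raises(ValueError, match="i_norm"):
        RampPairs(ca=np.array([2.0, 1.0]), i_norm=np.array([1.5, 0.5]),
                  t=np.array([0.0, 5.0]), imax=100.0)
    with pytest.raises(ValueError, match="decrease"):
        RampPairs(ca=np.array([1.0, 2.0]), i_norm=np.array([0.5, 0.6]),
                  t=np.array([0.0, 5.0]), imax=100.0)
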