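"""Blocker-subtraction isolation, peak extraction and I-V assembly."""

import numpy as np
import pytest

from cardiosk.io_model import StepProtocol, Sweep, TimeSeries
from cardiosk.isk import (PairingError, build_iv, isolate_isk,
                          normalize_rundown, peak_in_window)
from cardiosk.simulate import (GatingParams, NoiseParams, preset,
                               simulate_experiment, simulate_sweep)


def _sweep(values, condition, cell="c1", cap=100.0, v=0.0, onset=10.0, dur=50.0):
    return Sweep(
        current=TimeSeries(0.0, 1.0, np.asarray(values, float), "pA"),
        protocol=StepProtocol(-40.0, v, onset, dur),
        capacitance=cap, condition=condition, cell_id=cell)


class TestIsolate:
    def test_identical_sweeps_give_zero(self):
        vals = np.sin(np.arange(100.0))
        out = isolate_isk(_sweep(vals, "baseline"), _sweep(vals, "APA"))
        assert np.allclose(out.i_sk.values, 0.0)

    def test_antisymmetry_and_linearity(self):
        a = np.exp(-np.arange(100.0) / 30.0)
        b = 0.2 * np.cos(np.arange(100.0) / 7.0)
        fwd = isolate_isk(_sweep(a + b, "baseline"), _sweep(b, "APA"))
        assert np.allclose(fwd.i_sk.values, a)  # exact subtraction linearity
        rev = isolate_isk(_sweep(b, "baseline"), _sweep(a + b, "UCL"))
        # swapping which trace carries the extra component flips the sign
        assert np.allclose(rev.i_sk.values, -a)

    def test_pairing_validation(self):
        pre = _sweep(np.zeros(100), "baseline")
        with pytest.raises(PairingError, match="cells"):
            isolate_isk(pre, _sweep(np.zeros(100), "APA", cell="c2"))
        with pytest.raises(PairingError, match="blocker"):
            isolate_isk(pre, _sweep(np.zeros(100), "ISO"))
        with pytest.raises(PairingError, match="mismatch"):
            isolate_isk(pre, _sweep(np.zeros(100), "APA", onset=20.0))

    def test_simulated_pair_recovers_injected_current(self, protocol, no_noise):
        b = preset("tab-baseline")
        pre = simulate_sweep(protocol, b["transient"], b["gating"], b["ica"],
                             no_noise, with_sk=True)
        post = simulate_sweep(protocol, b["transient"], b["gating"], b["ica"],
                              no_noise, with_sk=False, condition="baseline+APA")
        out = isolate_isk(pre.sweep, post.sweep)
        assert np.allclose(out.i_sk.values, pre.truth.i_sk, atol=1e-9)

    def test_noisy_pair_recovers_within_noise_floor(self, protocol):
        b = preset("tab-baseline")
        noise = NoiseParams(sigma_current=5.0, sigma_fluor_frac=0.0, seed=11)
        pre = simulate_sweep(protocol, b["transient"], b["gating"], b["ica"],
                             noise, with_sk=True)
        post = simulate_sweep(protocol, b["transient"], b["gating"], b["ica"],
                              noise, with_sk=False, condition="baseline+APA")
        out = isolate_isk(pre.sweep, post.sweep)
        rmse = np.sqrt(np.mean((out.i_sk.values - pre.truth.i_sk) ** 2))
        assert rmse <= 2.0 * noise.sigma_current


class TestPeakInWindow:
    def test_monotone_rising_trace_peaks_at_window_end(self):
        x = TimeSeries(0.0, 1.0, np.arange(50.0), "pA")
        amp, t_pk = peak_in_window(x, (10.0, 30.0), "outward")
        assert amp == 30.0 and t_pk == 30.0

    def test_equal_maxima_return_earlier(self):
        vals = np.zeros(50)
        vals[[10, 30]] = 7.0
        amp, t_pk = peak_in_window(TimeSeries(0.0, 1.0, vals, "pA"), (0.0, 49.0))
        assert amp == 7.0 and t_pk == 10.0

    def test_inward_polarity_reports_magnitude(self):
        vals = -np.sin(np.linspace(0, np.pi, 60)) * 200.0
        amp, t_pk = peak_in_window(TimeSeries(0.0, 1.0, vals, "pA"),
                                   (0.0, 59.0), "inward")
        assert np.isclose(amp, 200.0, rtol=1e-3)

    def test_empty_window_rejected(self):
        x = TimeSeries(0.0, 1.0, np.arange(10.0), "pA")
        with pytest.raises(ValueError):
            peak_in_window(x, (3.2, 3.3))


class TestBuildIV:
    def test_matches_simulator_internal_record(self, no_noise):
        volts = [-30.0, -10.0, 10.0]
        sim = simulate_experiment(volts, ["baseline"], seed=3, noise=no_noise)
        iv = build_iv(sim.experiment)
        cap = sim.experiment.sweeps[0].capacitance
        for v, density in zip(iv.voltages, iv.isk_density):
            truth = sim.truths[("cell01", "baseline", v)]
            assert np.isclose(density, truth.i_sk.max() / cap, rtol=1e-6)

    def test_doubling_capacitance_halves_density(self, no_noise):
        volts = [-10.0]
        sim = simulate_experiment(volts, ["baseline"], seed=3, noise=no_noise)
        iv1 = build_iv(sim.experiment)
        for s in sim.experiment.sweeps:
            s.capacitance *= 2.0
        iv2 = build_iv(sim.experiment)
        assert np.allclose(iv2.isk_density, iv1.isk_density / 2.0)
        assert np.allclose(iv2.ica_density, iv1.ica_density / 2.0)

    def test_peak_ca_increases_with_voltage_on_rising_amplitudes(self, no_noise):
        # below the bell centre the transient amplitude rises with V
        volts = [-30.0, -20.0, -10.0, 0.0]
        sim = simulate_experiment(volts, ["baseline"], seed=3, noise=no_noise)
        iv = build_iv(sim.experiment)
        assert np.all(np.diff(iv.peak_ca) > 0)

    def test_unmatched_pairs_are_listed(self, no_noise):
        sim = simulate_experiment([-10.0], ["baseline"], seed=3, noise=no_noise)
        pruned = [s for s in sim.experiment.sweeps if s.condition != "baseline"]
        from cardiosk.io_model import ExperimentSet
        with pytest.raises(PairingError, match="cell01"):
            build_iv(ExperimentSet(pruned))


class TestRundown:
    def test_constant_series_is_100_percent(self):
        out = normalize_rundown([(0.0, 300.0), (3.0, 300.0), (6.0, 300.0)], 3.0)
        assert np.allclose(out.normalized_amplitude, 100.0)

    def test_reference_arithmetic(self):
        out = normalize_rundown([(3.0, 500.0), (10.0, 400.0)], 3.0)
        assert np.allclose(out.normalized_amplitude, [100.0, 80.0])

    def test_scale_invariance(self):
        series = [(0.0, 220.0), (3.0, 410.0), (8.0, 300.0)]
        a = normalize_rundown(series, 3.0)
        b = normalize_rundown([(t, 3.7 * v) for t, v in series], 3.0)
        assert np.allclose(a.normalized_amplitude, b.normalized_amplitude)

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            normalize_rundown([(3.0, 0.0), (5.0, 10.0)], 3.0)
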