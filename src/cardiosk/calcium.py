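"""Fluorescence calibration and submembrane Ca2+ reconstruction.

Single-wavelength indicator calibration
---------------------------------------
Rhod-2 fluorescence is converted to bulk cytosolic calcium with the standard
pseudo-ratio equation

    [Ca2+]_i = Kd * (F - Fmin) / (Fmax - F)

with Kd = 1.58 uM for Rhod-2 and Fmin = Fmax / 15.  Fmax is measured per cell
by rupturing the patch pipette into 1 mM Ca2+ bath; if the baseline drifts the
same equation is applied to F/F0 with Fmax expressed on that scale.

Submembrane calcium
-------------------
SK channels sit in the sarcolemma outside the dyad and sense a calcium
concentration that leads the bulk transient.  The subsarcolemmal estimate adds
a diffusion-lag derivative term to the bulk signal,

    [Ca2+]_sm = [Ca2+]_i + gamma * d[Ca2+]_i/dt,        gamma = 110 ms,

with the derivative taken on a Savitzky-Golay smoothed trace (5-point window,
quadratic).  The forward formula amplifies noise and, worse, its decay tail is
not a faithful estimate once release stops; past the [Ca]_sm peak the estimate
is therefore continued as a single exponential that follows the decay of
[Ca2+]_i (same tau and baseline), anchored at the peak for continuity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .io_model import TimeSeries

__all__ = [
    "CalibrationParams",
    "SubmembraneParams",
    "ExpDecayFit",
    "CaTraces",
    "calibrate_fluorescence",
    "inverse_calibrate",
    "fit_single_exponential",
    "reconstruct_submembrane",
    "submembrane_forward",
    "CalibrationError",
    "NoDecayError",
    "FitConvergenceError",
]

log = logging.getLogger(__name__)

#: Rhod-2 dissociation constant (uM)
KD_RHOD2 = 1.58


class CalibrationError(ValueError):
    pass


class NoDecayError(ValueError):
    pass


class FitConvergenceError(RuntimeError):
    def __init__(self, message: str, p0: tuple[float, ...]):
        super().__init__(f"{message} (initializer: {p0})")
        self.p0 = p0


@dataclass
class CalibrationParams:
    """Pseudo-ratio calibration constants.

    ``mode`` records whether samples are absolute fluorescence or F/F0; the
    arithmetic is identical, the tag documents the scale ``fmax`` lives on.
    """

    fmax: float
    kd: float = KD_RHOD2
    fmin: float | None = None  # defaults to fmax / 15
    mode: str = "absolute_F"

    def __post_init__(self) -> None:
        if self.fmin is None:
            self.fmin = self.fmax / 15.0
        if not self.kd > 0:
            raise ValueError("kd must be > 0")
        if not (self.fmax > self.fmin > 0):
            raise ValueError("need fmax > fmin > 0")
        if self.mode not in ("absolute_F", "F_over_F0"):
            raise ValueError(f"unknown calibration mode {self.mode!r}")


def calibrate_fluorescence(f: TimeSeries, p: CalibrationParams) -> TimeSeries:
    """Convert fluorescence (a.u.) to [Ca2+]_i (uM).

    Samples below Fmin (noise) are clipped to 0 uM with a logged count;
    samples at or above Fmax are unphysical for the pseudo-ratio and raise.
    """
    F = f.values
    at_max = np.flatnonzero(F >= p.fmax)
    if at_max.size:
        raise CalibrationError(
            f"fluorescence at/above Fmax at index {int(at_max[0])}"
        )
    below = F < p.fmin
    ca = p.kd * (F - p.fmin) / (p.fmax - F)
    if below.any():
        log.warning("calibrate_fluorescence: %d samples below Fmin clipped to 0 uM",
                    int(below.sum()))
        ca = np.where(below, 0.0, ca)
    return f.with_values(ca, unit="uM")


def inverse_calibrate(ca: TimeSeries, p: CalibrationParams) -> TimeSeries:
    """Algebraic inverse of the calibration: [Ca2+] (uM) -> fluorescence.

    F = (Fmax*ca + Kd*Fmin) / (ca + Kd); maps [0, inf) onto [Fmin, Fmax).
    Used by the simulator to synthesize dye signals.
    """
    c = ca.values
    if np.any(c < 0):
        raise ValueError("inverse_calibrate requires [Ca2+] >= 0")
    F = (p.fmax * c + p.kd * p.fmin) / (c + p.kd)
    return ca.with_values(F, unit="a.u.")


@dataclass
class ExpDecayFit:
    """baseline + amplitude * exp(-(t - t_start)/tau), fitted over [t_start, end]."""

    amplitude: float
    tau: float
    baseline: float
    t_start: float
    rmse: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be > 0")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.baseline + self.amplitude * np.exp(-(np.asarray(t) - self.t_start) / self.tau)


def fit_single_exponential(x: TimeSeries, t_start: float) -> ExpDecayFit:
    """Least-squares single-exponential decay fit from ``t_start`` to the end.

    Preconditions: >= 10 samples after t_start and a decaying segment (the
    mean of the last quartile below the mean of the first quartile).
    """
    sl = x.window_slice(t_start, x.t_end)
    t = x.t[sl]
    y = x.values[sl]
    if y.size < 10:
        raise ValueError(f"need >= 10 samples after t_start, got {y.size}")
    q = max(1, y.size // 4)
    if not np.mean(y[-q:]) < np.mean(y[:q]):
        raise NoDecayError("segment after t_start does not decay")

    b0 = float(np.mean(y[-max(1, y.size // 10):]))
    a0 = float(y[0] - b0)
    # tau guess: first crossing of baseline + amplitude/e
    thresh = b0 + a0 / np.e
    crossed = np.flatnonzero(y <= thresh) if a0 > 0 else np.flatnonzero(y >= thresh)
    tau0 = float(t[crossed[0]] - t[0]) if crossed.size and crossed[0] > 0 else (t[-1] - t[0]) / 3.0
    tau0 = max(tau0, x.dt)
    p0 = (a0, tau0, b0)

    def model(tt, a, tau, b):
        return b + a * np.exp(-(tt - t_start) / tau)

    try:
        popt, _ = curve_fit(
            model, t, y, p0=p0,
            bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitConvergenceError(f"single-exponential fit failed: {exc}", p0) from exc
    a, tau, b = (float(v) for v in popt)
    rmse = float(np.sqrt(np.mean((model(t, a, tau, b) - y) ** 2)))
    return ExpDecayFit(amplitude=a, tau=tau, baseline=b, t_start=float(t_start), rmse=rmse)


@dataclass
class SubmembraneParams:
    """Knobs of the submembrane reconstruction.

    gamma is the diffusion-lag constant (ms); sg_window/sg_polyorder control
    the Savitzky-Golay smoother applied before differentiation.
    """

    gamma: float = 110.0
    sg_window: int = 5
    sg_polyorder: int = 2
    smoothing_applied: bool = True

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.sg_window < 3 or self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd and >= 3")
        if not (0 < self.sg_polyorder < self.sg_window):
            raise ValueError("need 0 < sg_polyorder < sg_window")


@dataclass
class CaTraces:
    """Calibrated bulk and reconstructed submembrane Ca2+ on a shared time base."""

    ca_i: TimeSeries
    ca_sm: TimeSeries
    decay_fit: ExpDecayFit | None
    params: SubmembraneParams
    raw_sm: TimeSeries | None = None  # pre-splice forward estimate, kept for QC


def _smooth(values: np.ndarray, p: SubmembraneParams) -> np.ndarray:
    if not p.smoothing_applied:
        return values
    return savgol_filter(values, p.sg_window, p.sg_polyorder, mode="interp")


def submembrane_forward(ca_i: TimeSeries, p: SubmembraneParams) -> TimeSeries:
    """Forward estimate ca_i + gamma * d(ca_i)/dt, no decay splice.

    The derivative is central differences on the smoothed trace (one-sided at
    the edges); the gamma-term is added to the *raw* bulk trace.
    """
    if ca_i.values.size <= p.sg_window:
        raise ValueError("trace shorter than the smoothing window")
    smoothed = _smooth(ca_i.values, p)
    deriv = np.gradient(smoothed, ca_i.dt, edge_order=1)
    return ca_i.with_values(ca_i.values + p.gamma * deriv, unit="uM")


def reconstruct_submembrane(ca_i: TimeSeries, p: SubmembraneParams | None = None) -> CaTraces:
    """Reconstruct [Ca2+]_sm from a calibrated bulk transient.

    Rising phase and peak come from the forward formula; past the peak the
    estimate decays as a single exponential with the tau and baseline of the
    bulk-decay fit, anchored at the forward-estimate peak.  The peak is
    located and read on the Savitzky-Golay-smoothed forward estimate: the
    gamma-amplified derivative noise would otherwise make the raw one-sample
    maximum an upward-biased anchor for the whole decay.  A flat input (no
    derivative signal anywhere) is returned unchanged — the gamma-term
    vanishes and there is no decay to splice.
    """
    if p is None:
        p = SubmembraneParams()
    raw_sm = submembrane_forward(ca_i, p)
    ci = ca_i.values

    span = float(np.ptp(ci))
    if span <= 1e-12 * max(1.0, float(np.max(np.abs(ci)))):
        # constant input: derivative is zero, ca_sm == ca_i
        return CaTraces(ca_i=ca_i, ca_sm=raw_sm, decay_fit=None, params=p,
                        raw_sm=raw_sm)

    # locate the [Ca]sm peak on a smoothed copy (the gamma-amplified
    # derivative noise makes the raw single-sample maximum unreliable)
    raw_for_peak = _smooth(raw_sm.values, p)
    i_pk_raw = int(np.argmax(raw_for_peak))
    t_pk_raw = raw_sm.t[i_pk_raw]
    pk_raw = float(raw_for_peak[i_pk_raw])

    # decay of the bulk transient, fitted from its own peak
    i_pk_bulk = int(np.argmax(ci))
    if ci.size - i_pk_bulk < 10:
        raise NoDecayError("bulk [Ca2+] peaks at the trace end: no decay phase")
    fit = fit_single_exponential(ca_i, float(ca_i.t[i_pk_bulk]))

    t = raw_sm.t
    sm = raw_sm.values.copy()
    tail = t > t_pk_raw
    sm[tail] = fit.baseline + (pk_raw - fit.baseline) * np.exp(-(t[tail] - t_pk_raw) / fit.tau)
    neg = sm < 0
    if neg.any():
        log.warning("reconstruct_submembrane: %d negative samples clipped to 0",
                    int(neg.sum()))
        sm = np.where(neg, 0.0, sm)
    return CaTraces(
        ca_i=ca_i,
        ca_sm=ca_i.with_values(sm, unit="uM"),
        decay_fit=fit,
        params=p,
        raw_sm=raw_sm,
    )
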