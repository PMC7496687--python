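"""In-situ Ca2+ sensitivity of the SK current and biphasic timing metrics.

The decaying phase of a depolarization-evoked calcium transient is a slow,
monotone [Ca2+] ramp.  Pairing each post-peak I_SK sample with the
simultaneous [Ca2+] sample yields a dose-response cloud that is fitted with
the activation Hill equation

    I / Imax = 1 / (1 + (EC50 / [Ca2+])^h)

Only the decay phase is used: there the voltage-dependent inhibition by high
Ca2+ has relaxed and the bulk and submembrane concentrations track each other,
so the fit reads out the activation arm alone.  Imax is by convention the peak
I_SK of the same cell under beta-adrenergic stimulation (the least inhibited,
hence most nearly saturated, current); when no such reference exists the
sweep's own peak is used and the fit is flagged.

Timing metrics quantify the biphasic signature: I_SK peaks while [Ca2+]_sm is
still rising, so time-to-peak of I_SK precedes that of [Ca2+]_sm and the
submembrane concentration at the I_SK peak sits below its own maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .io_model import TimeSeries

__all__ = [
    "RampPairs",
    "HillFit",
    "InhibitionFit",
    "TimingMetrics",
    "extract_ramp",
    "fit_hill",
    "fit_inhibition",
    "timing_metrics",
    "RampError",
]

# multistart initializers for the Hill fit (EC50 in uM x Hill coefficient)
_EC50_STARTS = (0.2, 0.5, 1.0)
_H_STARTS = (1.0, 2.0, 4.0)

EC50_RELIABLE_RANGE = (1e-3, 1e3)  # uM


class RampError(ValueError):
    pass


@dataclass
class RampPairs:
    """Simultaneous ([Ca2+], I/Imax) samples from the transient decay."""

    ca: np.ndarray        # uM, decreasing
    i_norm: np.ndarray    # dimensionless
    t: np.ndarray         # ms
    imax: float           # pA, the normalization reference

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, float)
        self.i_norm = np.asarray(self.i_norm, float)
        self.t = np.asarray(self.t, float)
        if not (self.ca.size == self.i_norm.size == self.t.size):
            raise ValueError("incongruent ramp arrays")
        if np.any(self.i_norm < -0.05) or np.any(self.i_norm > 1.05):
            raise ValueError("i_norm outside [-0.05, 1.05]")
        if self.ca.size >= 2 and not self.ca[-1] < self.ca[0]:
            raise ValueError("ca does not decrease overall")


def extract_ramp(
    isk: TimeSeries,
    ca: TimeSeries,
    imax: float,
    t_end: float | None = None,
) -> RampPairs:
    """Pair post-peak I_SK with the decaying [Ca2+] ramp.

    Pairs run from the I_SK peak sample to ``t_end`` (default: end of trace).
    Non-monotone jitter is handled by monotone cleanup — any sample whose
    [Ca2+] is not strictly below the lowest kept so far is dropped — rather
    than smoothing, preserving the measured pairing.
    """
    if not imax > 0:
        raise ValueError("imax must be > 0")
    if not isk.same_time_base(ca):
        raise RampError("isk and ca must share a time base (resample first)")
    stop = isk.values.size if t_end is None else isk.window_slice(isk.t0, t_end).stop
    i_pk = int(np.argmax(isk.values[:stop]))
    if i_pk >= stop - 1:
        raise RampError("I_SK peak at trace end: no decay phase to pair")
    keep = [i_pk]
    low = ca.values[i_pk]
    rising_only = True
    for i in range(i_pk + 1, stop):
        c = ca.values[i]
        if c < low and c > 0:
            keep.append(i)
            low = c
            rising_only = False
    if rising_only:
        raise RampError("[Ca2+] never decreases after the I_SK peak; all points dropped")
    idx = np.array(keep)
    return RampPairs(
        ca=ca.values[idx],
        i_norm=isk.values[idx] / imax,
        t=isk.t[idx],
        imax=float(imax),
    )


@dataclass
class HillFit:
    ec50: float           # uM
    h: float              # Hill coefficient
    imax_used: float      # pA
    rmse: float
    n_points: int
    reliable: bool = True

    def __post_init__(self) -> None:
        if not (self.ec50 > 0 and self.h > 0):
            raise ValueError("ec50 and h must be > 0")


def _hill(ca: np.ndarray, ec50: float, h: float) -> np.ndarray:
    return 1.0 / (1.0 + (ec50 / ca) ** h)


def fit_hill(pairs: RampPairs) -> HillFit:
    """Unweighted least-squares activation Hill fit of a decay ramp.

    Requires >= 8 points spanning at least a 3-fold [Ca2+] range.  The fit is
    multistarted over a small EC50 x h grid and the lowest-RMSE solution is
    returned; an EC50 outside [1e-3, 1e3] uM is flagged unreliable.
    """
    mask = pairs.ca > 0
    ca, i = pairs.ca[mask], pairs.i_norm[mask]
    if ca.size < 8:
        raise RampError(f"need >= 8 positive-[Ca2+] points, got {ca.size}")
    span = float(np.max(ca) / np.min(ca))
    if span < 3.0:
        raise RampError(f"[Ca2+] range spans only {span:.2f}-fold; need >= 3")

    best = None
    errors: list[str] = []
    for e0 in _EC50_STARTS:
        for h0 in _H_STARTS:
            try:
                popt, _ = curve_fit(
                    _hill, ca, i, p0=(e0, h0),
                    bounds=([1e-6, 1e-3], [1e6, 50.0]), maxfev=20000,
                )
            except RuntimeError as exc:
                errors.append(f"start ({e0}, {h0}): {exc}")
                continue
            rmse = float(np.sqrt(np.mean((_hill(ca, *popt) - i) ** 2)))
            if best is None or rmse < best[1]:
                best = (popt, rmse)
    if best is None:
        raise RuntimeError("Hill fit failed from all starts: " + "; ".join(errors))
    (ec50, h), rmse = best
    reliable = EC50_RELIABLE_RANGE[0] <= ec50 <= EC50_RELIABLE_RANGE[1]
    return HillFit(ec50=float(ec50), h=float(h), imax_used=pairs.imax,
                   rmse=rmse, n_points=int(ca.size), reliable=bool(reliable))


@dataclass
class InhibitionFit:
    """Descending-limb fit Po = amplitude / (1 + ([Ca2+]/IC50)^h)."""

    ic50: float     # uM
    h: float
    amplitude: float
    rmse: float
    n_points: int


def fit_inhibition(ca: np.ndarray, po: np.ndarray) -> InhibitionFit:
    """Fit the inhibitory arm of a biphasic Po([Ca2+]) curve.

    Expects samples on the descending limb (above the Po maximum), where
    activation is saturated and Po ~ A / (1 + (ca/IC50)^h).
    """
    ca = np.asarray(ca, float)
    po = np.asarray(po, float)
    if ca.size < 5:
        raise ValueError("need >= 5 points on the descending limb")

    def model(c, ic50, h, a):
        return a / (1.0 + (c / ic50) ** h)

    p0 = (float(np.median(ca)), 2.0, float(np.max(po)))
    popt, _ = curve_fit(model, ca, po, p0=p0,
                        bounds=([1e-3, 0.1, 1e-6], [1e5, 20.0, 2.0]),
                        maxfev=20000)
    rmse = float(np.sqrt(np.mean((model(ca, *popt) - po) ** 2)))
    return InhibitionFit(ic50=float(popt[0]), h=float(popt[1]),
                         amplitude=float(popt[2]), rmse=rmse, n_points=int(ca.size))


@dataclass
class TimingMetrics:
    ttp_isk: float             # ms from step onset
    ttp_casm: float            # ms from step onset
    ca_sm_at_peak_isk: float   # uM
    ca_sm_peak: float          # uM

    def __post_init__(self) -> None:
        for name in ("ttp_isk", "ttp_casm", "ca_sm_at_peak_isk", "ca_sm_peak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def timing_metrics(isk: TimeSeries, ca_sm: TimeSeries, onset: float) -> TimingMetrics:
    """Time-to-peak of I_SK and [Ca2+]_sm (from step onset) and the
    submembrane concentration read at the I_SK peak sample.

    Peak times are first attainments of the maximum within a small relative
    tolerance (see :func:`cardiosk.isk.first_attainment`): a biphasically
    gated current revisits its optimum Ca2+ on the transient decay with
    near-identical amplitude, and the physiologically meaningful peak time
    is the first one.
    """
    from .isk import first_attainment

    if not (isk.t0 <= onset <= isk.t_end):
        raise ValueError(f"onset {onset} ms outside the I_SK trace span")
    if not isk.same_time_base(ca_sm):
        raise ValueError("isk and ca_sm must share a time base")
    sl = isk.window_slice(onset, isk.t_end)
    i_pk = sl.start + first_attainment(isk.values[sl])
    c_pk = sl.start + first_attainment(ca_sm.values[sl])
    return TimingMetrics(
        ttp_isk=float(isk.t[i_pk] - onset),
        ttp_casm=float(ca_sm.t[c_pk] - onset),
        ca_sm_at_peak_isk=float(ca_sm.values[i_pk]),
        ca_sm_peak=float(ca_sm.values[c_pk]),
    )
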