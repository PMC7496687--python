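"""Blocker-subtraction isolation of the SK current and I-V summaries.

I_SK is defined operationally: the component of whole-cell current removed by
a selective SK blocker (apamin or UCL-1684).  Subtracting the post-blocker
trace from the pre-blocker trace of the same cell and step leaves the
blocker-sensitive current; the post-blocker trace itself is kept as the
residual (L-type Ca2+ current plus leak).  No filtering or realignment is
applied — protocol timing must match exactly, so misaligned pairs fail loudly
instead of producing subtraction artefacts.

Per-voltage summaries report peak outward I_SK density, peak inward residual
density (pA/pF) and peak calibrated [Ca2+], pooled over cells as mean +/- SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calcium import CalibrationParams, calibrate_fluorescence, KD_RHOD2
from .io_model import ExperimentSet, Sweep, TimeSeries

__all__ = [
    "IsolatedCurrent",
    "IVCurve",
    "RundownSeries",
    "isolate_isk",
    "peak_in_window",
    "first_attainment",
    "build_iv",
    "normalize_rundown",
    "PairingError",
]

BLOCKERS = ("APA", "UCL")


class PairingError(ValueError):
    pass


@dataclass
class IsolatedCurrent:
    i_sk: TimeSeries          # pre - post (pA)
    i_residual: TimeSeries    # the post-blocker trace (I_Ca + leak)
    step_potential: float
    capacitance: float


def isolate_isk(pre: Sweep, post: Sweep) -> IsolatedCurrent:
    """Subtract post-blocker from pre-blocker current of the same cell/step."""
    if pre.cell_id != post.cell_id:
        raise PairingError(
            f"different cells: {pre.cell_id!r} vs {post.cell_id!r}"
        )
    tokens = post.condition.split("+")
    if not any(b in tokens for b in BLOCKERS):
        raise PairingError(
            f"post sweep condition {post.condition!r} does not mark a blocker"
        )
    if not pre.protocol.matches(post.protocol):
        raise PairingError(
            "protocol mismatch between pre and post sweeps "
            f"(onset {pre.protocol.step_onset} vs {post.protocol.step_onset} ms, "
            f"duration {pre.protocol.step_duration} vs {post.protocol.step_duration} ms, "
            f"step {pre.protocol.step_potential} vs {post.protocol.step_potential} mV)"
        )
    if not pre.current.same_time_base(post.current):
        raise PairingError("pre/post current traces are not on the same time base")
    i_sk = pre.current.with_values(pre.current.values - post.current.values)
    return IsolatedCurrent(
        i_sk=i_sk,
        i_residual=post.current,
        step_potential=pre.protocol.step_potential,
        capacitance=pre.capacitance,
    )


def first_attainment(values: np.ndarray, tie_rtol: float = 5e-3) -> int:
    """Index of the first sample within ``tie_rtol`` of the maximum.

    Peak *times* of plateaued or twin-peaked signals are ill-conditioned: a
    biphasically gated current crosses its optimal Ca2+ twice (rise and
    decay) with near-identical amplitudes, and which discrete sample wins by
    a fraction of a percent is arbitrary.  The reported peak time is
    therefore the first attainment of the maximum within a small fraction of
    the signal span; exact ties break earliest as a special case.
    """
    mx = float(np.max(values))
    span = float(np.ptp(values))
    return int(np.argmax(values >= mx - tie_rtol * span))


def peak_in_window(
    x: TimeSeries, window: tuple[float, float], polarity: str = "outward",
    tie_rtol: float = 5e-3,
) -> tuple[float, float]:
    """Peak amplitude and time within a window.

    ``outward`` takes the maximum, ``inward`` the minimum with the amplitude
    reported as a magnitude.  The peak time is the first sample attaining
    the extremum (within ``tie_rtol`` of the span; ties break earliest).
    Returns ``(amplitude_pA, t_peak_ms)``.
    """
    sl = x.window_slice(*window)
    seg = x.values[sl]
    t = x.t[sl]
    if polarity == "outward":
        i = first_attainment(seg, tie_rtol)
        return float(np.max(seg)), float(t[i])
    if polarity == "inward":
        i = first_attainment(-seg, tie_rtol)
        return float(abs(np.min(seg))), float(t[i])
    raise ValueError(f"polarity must be 'outward' or 'inward', got {polarity!r}")


@dataclass
class IVCurve:
    """Pooled per-voltage summary (mean +/- SD over cells)."""

    voltages: np.ndarray          # mV, strictly increasing
    isk_density: np.ndarray       # peak outward I_SK, pA/pF
    isk_density_sd: np.ndarray
    ica_density: np.ndarray       # peak inward residual magnitude, pA/pF
    ica_density_sd: np.ndarray
    peak_ca: np.ndarray           # uM (NaN where no fluorescence)
    peak_ca_sd: np.ndarray
    n: np.ndarray                 # cells per point

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.voltages) > 0):
            raise ValueError("voltages must be strictly increasing")
        lengths = {len(getattr(self, f)) for f in (
            "voltages", "isk_density", "isk_density_sd", "ica_density",
            "ica_density_sd", "peak_ca", "peak_ca_sd", "n")}
        if len(lengths) != 1:
            raise ValueError("incongruent IVCurve arrays")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "voltage_mV": self.voltages,
            "isk_pApF_mean": self.isk_density,
            "isk_pApF_sd": self.isk_density_sd,
            "ica_pApF_mean": self.ica_density,
            "ica_pApF_sd": self.ica_density_sd,
            "peak_ca_uM_mean": self.peak_ca,
            "peak_ca_uM_sd": self.peak_ca_sd,
            "n": self.n,
        })


def _pre_condition_for(post_condition: str, blocker: str) -> str:
    tokens = [tok for tok in post_condition.split("+") if tok != blocker]
    return "+".join(tokens) if tokens else "baseline"


def build_iv(
    expset: ExperimentSet,
    blocker: str = "APA",
    kd: float = KD_RHOD2,
) -> IVCurve:
    """Assemble the pooled I-V / peak-[Ca2+]-V summary for one blocker.

    For every (cell, voltage) a pre/post pair is required: the post sweep's
    condition contains the blocker tag and the pre sweep carries the same
    condition with the blocker removed (``ISO+APA`` pairs with ``ISO``,
    ``APA`` with ``baseline``).  Unmatched pairs are reported in the error.
    """
    if blocker not in BLOCKERS:
        raise ValueError(f"unknown blocker {blocker!r}; expected one of {BLOCKERS}")
    groups = expset.groups()
    # collect per-voltage, per-cell measurements
    per_v: dict[float, dict[str, tuple[float, float, float]]] = {}
    unmatched: list[str] = []
    for (cell, cond, v), sweeps in groups.items():
        tokens = cond.split("+")
        if blocker not in tokens:
            continue
        pre_cond = _pre_condition_for(cond, blocker)
        pre_candidates = groups.get((cell, pre_cond, v), [])
        if not pre_candidates:
            unmatched.append(f"cell={cell} V={v:g} mV: no pre sweep {pre_cond!r}")
            continue
        pre, post = pre_candidates[0], sweeps[0]
        iso = isolate_isk(pre, post)
        window = pre.protocol.window
        isk_pk, _ = peak_in_window(iso.i_sk, window, "outward")
        ica_pk, _ = peak_in_window(iso.i_residual, window, "inward")
        ca_pk = np.nan
        if pre.fluorescence is not None:
            if pre.fmax is None:
                raise ValueError(f"fmax missing for cell_id={cell}")
            ca = calibrate_fluorescence(
                pre.fluorescence, CalibrationParams(fmax=pre.fmax, kd=kd))
            ca_pk, _ = peak_in_window(ca, window, "outward")
        per_v.setdefault(v, {})[cell] = (
            isk_pk / iso.capacitance, ica_pk / iso.capacitance, ca_pk)
    if unmatched:
        raise PairingError("unmatched blocker pairs: " + "; ".join(sorted(unmatched)))
    if not per_v:
        raise PairingError(f"no sweeps with blocker {blocker!r} in the set")

    voltages = np.array(sorted(per_v))

    def pooled(idx: int) -> tuple[np.ndarray, np.ndarray]:
        mean, sd = [], []
        for v in voltages:
            vals = np.array([m[idx] for m in per_v[v].values()])
            mean.append(np.nanmean(vals) if not np.all(np.isnan(vals)) else np.nan)
            sd.append(np.nanstd(vals, ddof=1) if np.sum(~np.isnan(vals)) > 1 else 0.0)
        return np.array(mean), np.array(sd)

    isk_m, isk_s = pooled(0)
    ica_m, ica_s = pooled(1)
    ca_m, ca_s = pooled(2)
    n = np.array([len(per_v[v]) for v in voltages])
    return IVCurve(voltages, isk_m, isk_s, ica_m, ica_s, ca_m, ca_s, n)


@dataclass
class RundownSeries:
    """Current amplitudes expressed as % of the amplitude at a reference time."""

    times: np.ndarray                 # min
    normalized_amplitude: np.ndarray  # % of reference
    reference_time: float


def normalize_rundown(
    amplitudes: list[tuple[float, float]], reference_time: float
) -> RundownSeries:
    """Express each (time_min, amplitude_pA) as % of the reference amplitude."""
    times = np.array([t for t, _ in amplitudes], float)
    amps = np.array([a for _, a in amplitudes], float)
    hit = np.flatnonzero(np.isclose(times, reference_time, rtol=0, atol=1e-9))
    if not hit.size:
        raise ValueError(f"reference_time {reference_time} min not present in series")
    ref = amps[hit[0]]
    if ref == 0:
        raise ZeroDivisionError("reference amplitude is zero")
    return RundownSeries(
        times=times,
        normalized_amplitude=100.0 * amps / ref,
        reference_time=float(reference_time),
    )
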