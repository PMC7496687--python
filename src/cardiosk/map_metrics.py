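"""Optical-mapping metrics: activation, APD maps, conduction velocity.

Movies of a voltage-sensitive dye (100 x 100 pixels, 2000 frames/s, 1.5 x 1.5
cm field of view by default) are reduced per pixel to an activation time (time
of maximum dF/dt of the upstroke) and an action-potential duration at a
repolarization level (75% of AP amplitude by default, APD90 also common).
Conduction velocity comes from a single global plane fit to the activation
map: for activation T(x, y) ~ a + b*x + c*y the wavefront speed is
1/||(b, c)|| in mm/ms, reported in cm/s.

Pixels are masked by signal-to-noise (AP amplitude >= 5x the pre-upstroke
baseline SD).  Di-4-ANEPPS fluorescence decreases on depolarization; movies
carrying ``polarity="down"`` are negated so depolarization is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .io_model import TimeSeries

__all__ = [
    "VoltageMap",
    "APDMap",
    "CVResult",
    "activation_time",
    "apd_at_level",
    "conduction_velocity",
    "build_apd_map",
    "read_voltage_map",
    "write_voltage_map",
    "FlatTraceError",
]

#: default amplitude threshold: 5x baseline SD
SNR_MASK_FACTOR = 5.0
#: plane-fit residual (ms) above which the single-wavefront assumption is suspect
CV_RMSE_WARN_MS = 2.0


class FlatTraceError(ValueError):
    """No upstroke above the noise threshold in the window."""


@dataclass
class VoltageMap:
    """Frame-stacked optical movie (time x rows x cols, a.u.)."""

    frames: np.ndarray
    frame_interval: float = 0.5     # ms (2000 frames/s)
    pixel_pitch: float = 0.15       # mm (1.5 cm / 100 px)
    pacing_cycle_length: float | None = None
    polarity: str = "up"            # "down": dye signal decreases on depolarization

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (time, rows, cols)")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if self.polarity not in ("up", "down"):
            raise ValueError("polarity must be 'up' or 'down'")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def pixel(self, row: int, col: int) -> TimeSeries:
        vals = self.frames[:, row, col]
        if self.polarity == "down":
            vals = -vals
        return TimeSeries(0.0, self.frame_interval, vals, "a.u.")


@dataclass
class APDMap:
    apd: np.ndarray           # ms, valid where mask
    level: float              # % repolarization
    activation: np.ndarray    # ms, valid where mask
    mask: np.ndarray          # analyzable pixels

    def __post_init__(self) -> None:
        if not (0 < self.level < 100):
            raise ValueError("level must be in (0, 100)")
        if np.any(self.apd[self.mask] <= 0):
            raise ValueError("non-positive APD inside the mask")


def _derivative(values: np.ndarray, dt: float) -> np.ndarray:
    return np.gradient(values, dt, edge_order=1)


def activation_time(
    trace: TimeSeries,
    window: tuple[float, float],
    noise_threshold: float = 0.0,
) -> float:
    """Time of maximum dF/dt within the window (earliest on ties).

    ``noise_threshold`` is a derivative floor (a.u./ms); a trace whose maximum
    derivative does not exceed it has no detectable upstroke and raises
    :class:`FlatTraceError` so map builders can mask the pixel.
    """
    sl = trace.window_slice(*window)
    d = _derivative(trace.values, trace.dt)[sl]
    i = int(np.argmax(d))
    if d[i] <= noise_threshold:
        raise FlatTraceError("no upstroke above the derivative threshold")
    return float(trace.t[sl][i])


def apd_at_level(
    trace: TimeSeries,
    level: float,
    window: tuple[float, float],
) -> float:
    """AP duration at ``level`` % repolarization of the AP amplitude.

    amplitude = peak - pre-upstroke baseline; the AP ends at the first time
    after the peak at which the signal falls below peak - level%*amplitude,
    located with sub-frame linear interpolation.  APD is measured from the
    activation time (max dF/dt).
    """
    if not (0 < level < 100):
        raise ValueError("level must be in (0, 100) percent")
    t_act = activation_time(trace, window)
    sl = trace.window_slice(*window)
    seg = trace.values[sl]
    t = trace.t[sl]
    # pre-upstroke baseline: samples up to just before the activation point
    pre = seg[t < t_act - trace.dt]
    baseline = float(np.median(pre)) if pre.size else float(seg[0])
    i_pk = int(np.argmax(seg))
    peak = float(seg[i_pk])
    amplitude = peak - baseline
    if amplitude <= 0:
        raise FlatTraceError("non-positive AP amplitude")
    threshold = peak - (level / 100.0) * amplitude
    below = np.flatnonzero(seg[i_pk:] < threshold)
    if not below.size:
        raise FlatTraceError(f"no {level:g}% repolarization before window end")
    j = i_pk + int(below[0])
    if j == i_pk:  # peak sample already below (cannot happen unless level<=0)
        t_cross = t[j]
    else:
        y0, y1 = seg[j - 1], seg[j]
        frac = (y0 - threshold) / (y0 - y1)
        t_cross = t[j - 1] + frac * trace.dt
    return float(t_cross - t_act)


@dataclass
class CVResult:
    cv: float                 # cm/s
    gradient: np.ndarray      # (b, c) ms/mm along (col, row)
    rmse: float               # plane-fit residual, ms
    plane_ok: bool            # residual below CV_RMSE_WARN_MS


def conduction_velocity(
    activation: np.ndarray,
    mask: np.ndarray,
    pixel_pitch: float,
    rmse_warn_ms: float = CV_RMSE_WARN_MS,
) -> CVResult:
    """Global wavefront speed from a plane fit to the activation map.

    Fits T = a + b*x + c*y (x = col, y = row, in mm) over unmasked pixels by
    least squares; CV = 1/||(b, c)|| converted to cm/s.  A radial or colliding
    wavefront leaves a large residual, flagged via ``plane_ok``.
    """
    activation = np.asarray(activation, float)
    mask = np.asarray(mask, bool)
    rows, cols = np.nonzero(mask)
    if rows.size < 10:
        raise ValueError(f"need >= 10 unmasked pixels, got {rows.size}")
    T = activation[rows, cols]
    if np.ptp(T) <= 0:
        raise ValueError("uniform activation: wavefront direction undefined")
    x = cols * pixel_pitch
    y = rows * pixel_pitch
    A = np.column_stack([np.ones_like(x), x, y])
    coef, *_ = np.linalg.lstsq(A, T, rcond=None)
    grad = coef[1:]
    slowness = float(np.hypot(*grad))  # ms/mm
    if slowness <= 0:
        raise ValueError("rank-deficient plane fit: zero activation gradient")
    resid = A @ coef - T
    rmse = float(np.sqrt(np.mean(resid**2)))
    cv_mm_per_ms = 1.0 / slowness
    return CVResult(
        cv=cv_mm_per_ms * 100.0,  # mm/ms -> cm/s
        gradient=grad,
        rmse=rmse,
        plane_ok=rmse <= rmse_warn_ms,
    )


def _mean_filter_3x3(frames: np.ndarray) -> np.ndarray:
    """3x3 spatial mean with edge replication, applied frame-wise."""
    padded = np.pad(frames, ((0, 0), (1, 1), (1, 1)), mode="edge")
    out = np.zeros_like(frames)
    for dr in (0, 1, 2):
        for dc in (0, 1, 2):
            out += padded[:, dr:dr + frames.shape[1], dc:dc + frames.shape[2]]
    return out / 9.0


def build_apd_map(
    vmap: VoltageMap,
    level: float = 75.0,
    window: tuple[float, float] | None = None,
    snr_factor: float = SNR_MASK_FACTOR,
    spatial_filter: bool = False,
) -> APDMap:
    """Per-pixel activation and APD maps with SNR masking.

    A pixel is analyzable when its AP amplitude is at least ``snr_factor``
    times the SD of its pre-upstroke baseline (first tenth of the window).
    ``spatial_filter`` applies an optional 3x3 mean filter before extraction
    (off by default).
    """
    frames = vmap.frames if not spatial_filter else _mean_filter_3x3(vmap.frames)
    vm = VoltageMap(frames, vmap.frame_interval, vmap.pixel_pitch,
                    vmap.pacing_cycle_length, vmap.polarity)
    if window is None:
        window = (0.0, vm.frame_interval * (vm.n_frames - 1))
    n_rows, n_cols = vm.frames.shape[1:]
    apd = np.full((n_rows, n_cols), np.nan)
    act = np.full((n_rows, n_cols), np.nan)
    mask = np.zeros((n_rows, n_cols), bool)
    for r in range(n_rows):
        for c in range(n_cols):
            trace = vm.pixel(r, c)
            sl = trace.window_slice(*window)
            seg = trace.values[sl]
            t_seg = trace.t[sl]
            try:
                t_act = activation_time(trace, window)
            except FlatTraceError:
                continue
            # SNR gate against the pre-upstroke baseline of this pixel
            pre = seg[t_seg < t_act - trace.dt]
            baseline = float(np.median(pre)) if pre.size else float(seg[0])
            base_sd = float(np.std(pre)) if pre.size >= 2 else 0.0
            amplitude = float(np.max(seg)) - baseline
            if amplitude <= 0 or amplitude < snr_factor * base_sd:
                continue
            try:
                apd[r, c] = apd_at_level(trace, level, window)
            except FlatTraceError:
                continue
            act[r, c] = t_act
            mask[r, c] = True
    return APDMap(apd=apd, level=level, activation=act, mask=mask)


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def write_voltage_map(vmap: VoltageMap, path: str) -> str:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=vmap.frames)
        f.attrs["frame_interval_ms"] = vmap.frame_interval
        f.attrs["pixel_pitch_mm"] = vmap.pixel_pitch
        f.attrs["polarity"] = vmap.polarity
        if vmap.pacing_cycle_length is not None:
            f.attrs["pacing_cycle_length_ms"] = vmap.pacing_cycle_length
    return path


def read_voltage_map(path: str) -> VoltageMap:
    with h5py.File(path, "r") as f:
        return VoltageMap(
            frames=f["frames"][...],
            frame_interval=float(f.attrs["frame_interval_ms"]),
            pixel_pitch=float(f.attrs["pixel_pitch_mm"]),
            pacing_cycle_length=(
                float(f.attrs["pacing_cycle_length_ms"])
                if "pacing_cycle_length_ms" in f.attrs else None
            ),
            polarity=str(f.attrs.get("polarity", "up")),
        )
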