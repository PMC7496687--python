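"""Data model and on-disk formats for voltage-clamp sweep experiments.

A recording session is a set of :class:`Sweep` objects, each pairing a
whole-cell current trace (pA) with an optional line-scan-averaged fluorescence
trace (a.u.) acquired under a square voltage-step protocol.  Sweeps are grouped
by ``(cell_id, condition, step_potential)``; the ``condition`` tag records the
pharmacology (``baseline``, ``ISO``, ``APA``, ``ISO+APA``, ...), which is how
downstream blocker-subtraction pairing works.

Time is milliseconds everywhere.  Currents are stored raw in pA (outward
positive); normalization to pA/pF happens only in analysis outputs.  Sampling
must be uniform — non-uniform input is an error, never silently resampled.

On disk an experiment is a directory with one JSON sidecar
(``experiment.json``) listing the sweeps and their metadata, plus one
two-column CSV (``time_ms,value``) per trace.  Numeric text is written at 17
significant digits so a write/read round trip is bit-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "StepProtocol",
    "Sweep",
    "ExperimentSet",
    "read_experiment",
    "write_experiment",
    "resample",
    "block_average",
]

_SIDECAR_NAME = "experiment.json"
_FORMAT_VERSION = 1

#: units a TimeSeries may carry
UNITS = ("pA", "a.u.", "uM", "mV", "ms")


class ExperimentFormatError(ValueError):
    """Raised for missing/contradictory metadata or malformed trace files."""


@dataclass
class TimeSeries:
    """Uniformly sampled signal with a time offset.

    Parameters
    ----------
    t0 : float
        Time of the first sample (ms).
    dt : float
        Sampling interval (ms), strictly positive.
    values : ndarray
        Samples; at least 2, all finite.
    unit : str
        Unit tag carried along (``pA``, ``a.u.``, ``uM``, ``mV``).
    """

    t0: float
    dt: float
    values: np.ndarray
    unit: str = "a.u."

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("TimeSeries needs a 1-D array of length >= 2")
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise ValueError(f"non-finite sample at index {bad}")

    @property
    def t(self) -> np.ndarray:
        """Sample times (ms)."""
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (self.values.size - 1)

    def covers(self, t_lo: float, t_hi: float) -> bool:
        return self.t0 <= t_lo and self.t_end >= t_hi

    def index_at(self, time_ms: float) -> int:
        """Index of the sample nearest ``time_ms``."""
        i = int(round((time_ms - self.t0) / self.dt))
        return min(max(i, 0), self.values.size - 1)

    def window_slice(self, t_lo: float, t_hi: float) -> slice:
        """Slice of samples with t_lo <= t <= t_hi (inclusive)."""
        if t_hi < t_lo:
            raise ValueError("empty window")
        lo = int(np.ceil((t_lo - self.t0) / self.dt - 1e-9))
        hi = int(np.floor((t_hi - self.t0) / self.dt + 1e-9))
        lo, hi = max(lo, 0), min(hi, self.values.size - 1)
        if hi < lo:
            raise ValueError(f"window [{t_lo}, {t_hi}] ms contains no samples")
        return slice(lo, hi + 1)

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "TimeSeries":
        return TimeSeries(self.t0, self.dt, np.asarray(values, float),
                          unit if unit is not None else self.unit)

    def same_time_base(self, other: "TimeSeries", rtol: float = 1e-9) -> bool:
        return (
            self.values.size == other.values.size
            and abs(self.t0 - other.t0) <= rtol * max(1.0, abs(self.t0))
            and abs(self.dt - other.dt) <= rtol * self.dt
        )

    def __eq__(self, other: object) -> bool:  # exact, for round-trip checks
        if not isinstance(other, TimeSeries):
            return NotImplemented
        return (
            self.t0 == other.t0
            and self.dt == other.dt
            and self.unit == other.unit
            and np.array_equal(self.values, other.values)
        )


def resample(ts: TimeSeries, ref: TimeSeries) -> TimeSeries:
    """Linearly interpolate ``ts`` onto the time base of ``ref``.

    Used to put a 5 kHz current trace and a 5 ms/line fluorescence-derived
    trace on a common grid before pairing them sample-by-sample.
    """
    vals = np.interp(ref.t, ts.t, ts.values)
    return TimeSeries(ref.t0, ref.dt, vals, ts.unit)


def block_average(ts: TimeSeries, ref: TimeSeries) -> TimeSeries:
    """Average ``ts`` within each sampling bin of the coarser ``ref`` grid.

    Explicit down-sampling for pairing a fast digitized current with a slow
    line-scan signal: every ``ref`` sample gets the mean of the ``ts``
    samples within +/- ref.dt/2 of it, which suppresses wide-band noise by
    the square root of the decimation factor (linear interpolation would
    keep the full single-sample noise).
    """
    if ref.dt <= ts.dt:
        return resample(ts, ref)
    out = np.empty(ref.values.size)
    half = ref.dt / 2.0
    for i, tc in enumerate(ref.t):
        sl = ts.window_slice(max(tc - half, ts.t0), min(tc + half, ts.t_end))
        out[i] = float(np.mean(ts.values[sl]))
    return TimeSeries(ref.t0, ref.dt, out, ts.unit)


@dataclass
class StepProtocol:
    """Square voltage-step protocol (all times ms, potentials mV)."""

    holding_potential: float
    step_potential: float
    step_onset: float
    step_duration: float
    inter_sweep_interval: float = 2000.0

    def __post_init__(self) -> None:
        if self.step_onset < 0:
            raise ValueError("step_onset must be >= 0")
        if not self.step_duration > 0:
            raise ValueError("step_duration must be > 0")

    @property
    def step_end(self) -> float:
        return self.step_onset + self.step_duration

    @property
    def window(self) -> tuple[float, float]:
        """The [onset, onset+duration] analysis window."""
        return (self.step_onset, self.step_end)

    def matches(self, other: "StepProtocol", atol: float = 1e-9) -> bool:
        """Timing-compatible for subtraction (potentials may differ by cond)."""
        return (
            abs(self.step_onset - other.step_onset) <= atol
            and abs(self.step_duration - other.step_duration) <= atol
            and abs(self.step_potential - other.step_potential) <= atol
        )


@dataclass(eq=False)
class Sweep:
    """One voltage-clamp episode.

    ``fmax``/``f0`` are the per-cell fluorescence calibration anchors (Fmax
    from pipette rupture; F0 baseline if the F/F0 convention is in use) and may
    be absent when no fluorescence was recorded.
    """

    current: TimeSeries
    protocol: StepProtocol
    capacitance: float
    condition: str
    cell_id: str
    fluorescence: TimeSeries | None = None
    fmax: float | None = None
    f0: float | None = None

    def __post_init__(self) -> None:
        if not self.capacitance > 0:
            raise ValueError(
                f"capacitance must be > 0 for cell_id={self.cell_id}"
            )
        if self.current.unit != "pA":
            raise ValueError("current trace must carry unit 'pA'")
        if self.fluorescence is not None and not self.fluorescence.covers(
            self.protocol.step_onset, self.protocol.step_end
        ):
            raise ValueError(
                "fluorescence trace does not cover the step window "
                f"for cell_id={self.cell_id}"
            )

    @property
    def key(self) -> tuple[str, str, float]:
        return (self.cell_id, self.condition, self.protocol.step_potential)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Sweep):
            return NotImplemented
        return (
            self.current == other.current
            and self.fluorescence == other.fluorescence
            and self.protocol == other.protocol
            and self.capacitance == other.capacitance
            and self.condition == other.condition
            and self.cell_id == other.cell_id
            and self.fmax == other.fmax
            and self.f0 == other.f0
        )


@dataclass(eq=False)
class ExperimentSet:
    """Collection of sweeps grouped by (cell_id, condition, step_potential)."""

    sweeps: list[Sweep] = field(default_factory=list)

    def __post_init__(self) -> None:
        caps: dict[str, float] = {}
        for s in self.sweeps:
            if s.cell_id in caps and caps[s.cell_id] != s.capacitance:
                raise ValueError(
                    f"inconsistent capacitance for cell_id={s.cell_id}: "
                    f"{caps[s.cell_id]} vs {s.capacitance} pF"
                )
            caps[s.cell_id] = s.capacitance

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self) -> Iterator[Sweep]:
        return iter(self.sweeps)

    def groups(self) -> dict[tuple[str, str, float], list[Sweep]]:
        """Partition of the sweeps by (cell, condition, voltage)."""
        out: dict[tuple[str, str, float], list[Sweep]] = {}
        for s in self.sweeps:
            out.setdefault(s.key, []).append(s)
        return out

    def cells(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sweeps:
            seen.setdefault(s.cell_id)
        return list(seen)

    def select(self, cell_id: str | None = None, condition: str | None = None,
               step_potential: float | None = None) -> list[Sweep]:
        out = []
        for s in self.sweeps:
            if cell_id is not None and s.cell_id != cell_id:
                continue
            if condition is not None and s.condition != condition:
                continue
            if step_potential is not None and s.protocol.step_potential != step_potential:
                continue
            out.append(s)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExperimentSet):
            return NotImplemented
        return self.sweeps == other.sweeps


# ---------------------------------------------------------------------------
# on-disk format
# ---------------------------------------------------------------------------

def _trace_filename(idx: int, sweep: Sweep, kind: str) -> str:
    cond = "".join(c if (c.isalnum() or c in "-_") else "-" for c in sweep.condition)
    v = sweep.protocol.step_potential
    vtag = f"m{abs(v):g}" if v < 0 else f"p{v:g}"
    return f"s{idx:03d}_{sweep.cell_id}_{cond}_{vtag}mV_{kind}.csv"


def _write_trace(path: Path, ts: TimeSeries) -> None:
    arr = np.column_stack([ts.t, ts.values])
    np.savetxt(path, arr, fmt="%.17g", delimiter=",",
               header="time_ms,value", comments="")


def _read_trace(path: Path, unit: str) -> TimeSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["time_ms", "value"]:
        raise ExperimentFormatError(f"{path.name}: expected header time_ms,value")
    t = df["time_ms"].to_numpy(float)
    v = df["value"].to_numpy(float)
    if not np.all(np.isfinite(v)):
        row = int(np.flatnonzero(~np.isfinite(v))[0])
        raise ExperimentFormatError(f"{path.name}: non-finite sample at row {row}")
    if t.size < 2:
        raise ExperimentFormatError(f"{path.name}: fewer than 2 samples")
    dts = np.diff(t)
    dt = dts[0]
    if not np.allclose(dts, dt, rtol=1e-9, atol=1e-9 * max(dt, 1.0)):
        raise ExperimentFormatError(f"{path.name}: non-uniform sampling interval")
    return TimeSeries(t[0], dt, v, unit)


def write_experiment(expset: ExperimentSet, path: str | Path) -> Path:
    """Write an experiment directory; deterministic layout, bit-stable text."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, s in enumerate(expset.sweeps):
        cur_name = _trace_filename(i, s, "current")
        _write_trace(path / cur_name, s.current)
        entry = {
            "cell_id": s.cell_id,
            "condition": s.condition,
            "capacitance_pF": s.capacitance,
            "holding_potential_mV": s.protocol.holding_potential,
            "step_potential_mV": s.protocol.step_potential,
            "step_onset_ms": s.protocol.step_onset,
            "step_duration_ms": s.protocol.step_duration,
            "inter_sweep_interval_ms": s.protocol.inter_sweep_interval,
            "current_file": cur_name,
            "current_t0_ms": s.current.t0,
            "current_dt_ms": s.current.dt,
        }
        if s.fluorescence is not None:
            flu_name = _trace_filename(i, s, "fluorescence")
            _write_trace(path / flu_name, s.fluorescence)
            entry["fluorescence_file"] = flu_name
            entry["fluorescence_t0_ms"] = s.fluorescence.t0
            entry["fluorescence_dt_ms"] = s.fluorescence.dt
        if s.fmax is not None:
            entry["fmax"] = s.fmax
        if s.f0 is not None:
            entry["f0"] = s.f0
        entries.append(entry)
    sidecar = {"format_version": _FORMAT_VERSION, "sweeps": entries}
    (path / _SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1) + "\n")
    return path


_REQUIRED_FIELDS = (
    "cell_id", "condition", "capacitance_pF", "holding_potential_mV",
    "step_potential_mV", "step_onset_ms", "step_duration_ms", "current_file",
)


def read_experiment(path: str | Path) -> ExperimentSet:
    """Load an experiment directory written by :func:`write_experiment`."""
    path = Path(path)
    sidecar_path = path / _SIDECAR_NAME
    if not sidecar_path.exists():
        raise ExperimentFormatError(f"no {_SIDECAR_NAME} in {path}")
    sidecar = json.loads(sidecar_path.read_text())
    sweeps: list[Sweep] = []
    for entry in sidecar.get("sweeps", []):
        for key in _REQUIRED_FIELDS:
            if key not in entry:
                cell = entry.get("cell_id", "<unknown>")
                raise ExperimentFormatError(
                    f"{key.replace('_pF', '').replace('_mV', '').replace('_ms', '')}"
                    f" missing for cell_id={cell}"
                )
        protocol = StepProtocol(
            holding_potential=entry["holding_potential_mV"],
            step_potential=entry["step_potential_mV"],
            step_onset=entry["step_onset_ms"],
            step_duration=entry["step_duration_ms"],
            inter_sweep_interval=entry.get("inter_sweep_interval_ms", 2000.0),
        )
        current = _read_trace(path / entry["current_file"], "pA")
        declared_dt = entry.get("current_dt_ms")
        if declared_dt is not None and abs(declared_dt - current.dt) > 1e-9 * declared_dt:
            raise ExperimentFormatError(
                f"dt contradictory for cell_id={entry['cell_id']}: sidecar "
                f"{declared_dt} ms vs trace {current.dt} ms"
            )
        fluor = None
        if "fluorescence_file" in entry:
            fluor = _read_trace(path / entry["fluorescence_file"], "a.u.")
        sweeps.append(Sweep(
            current=current,
            fluorescence=fluor,
            protocol=protocol,
            capacitance=entry["capacitance_pF"],
            condition=entry["condition"],
            cell_id=entry["cell_id"],
            fmax=entry.get("fmax"),
            f0=entry.get("f0"),
        ))
    return ExperimentSet(sweeps)
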