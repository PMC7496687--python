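"""Biphasic SK gating model and synthetic voltage-clamp experiment generator.

Gating model
------------
SK2 open probability is controlled by submembrane Ca2+ in a biphasic manner:
calmodulin-mediated activation by submicromolar Ca2+ and a voltage-dependent
inhibition by tens-of-micromolar Ca2+,

    Po(ca, V) = ca^h_act / (ca^h_act + EC50^h_act)
              * 1 / (1 + (ca / IC50(V))^h_inh)

    IC50(V) = phospho_factor * IC50_ref * exp(-(V - V_ref) / slope_mV)

Defaults: EC50 = 0.46 uM, h_act = 2.6 (the in-situ ramp estimates), IC50_ref
= 20 uM at V_ref = -40 mV with an e-fold decrease per 17 mV of
depolarization, h_inh = 2.  The exponential voltage dependence and its slope
are model choices: the slope is set so that by +30..+40 mV the IC50 falls
into the activation range, which reproduces the observed rectification (the
current nearly vanishes at +30 mV despite an undiminished Ca2+ transient).
PKA phosphorylation (S465) is modelled purely as multiplicative relief of
inhibition — ``phospho_factor`` scales IC50_ref and never touches the
activation arm, reflecting the finding that beta-adrenergic stimulation does
not change the affinity for activating submicromolar Ca2+.

Gating is instantaneous (SK kinetics are fast relative to the transient), so
I_SK(t) = g_total * Po(ca_sm(t), V) * (V - E_K), with E_K = -83.7 mV from the
5.4 / 140 mM K+ gradient at room temperature.

Synthetic sweeps
----------------
The calcium transient during a step is a phenomenological two-exponential
with a sigmoidal foot,

    ca_i(t') = rest + amp(V) * (1 - exp(-t'/tau_rise))^2 * exp(-t'/tau_decay)

whose voltage dependence amp(V) is a bell centred near 0 mV mimicking the
L-type current.  The squared rise gives the transient a smooth onset so the
derivative-boosted submembrane signal peaks tens of ms into the step rather
than instantaneously.  The simulator's ground-truth submembrane concentration
follows the forward diffusion-lag formula ca_i + gamma*d(ca_i)/dt up to its
peak and then relaxes to rest with the bulk decay constant — the same
submembrane model the reconstruction in :mod:`cardiosk.calcium` estimates.

The residual (blocker-insensitive) current is an L-type surrogate
g_ca * act(V) * exp(-t'/tau_inact) * (V - E_Ca), and the dye signal is the
algebraic inverse of the calibration applied to ca_i.  Gaussian noise is
added to the current (pA) and multiplicatively to the fluorescence.  Every
sweep draws its noise from a seed derived from
(master_seed, cell index, condition, voltage, phase) via
``numpy.random.SeedSequence`` spawn keys, so experiments are reproducible
sweep-by-sweep.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .calcium import CalibrationParams, inverse_calibrate
from .io_model import ExperimentSet, StepProtocol, Sweep, TimeSeries

__all__ = [
    "GatingParams",
    "TransientParams",
    "ICaParams",
    "NoiseParams",
    "GroundTruth",
    "SimulatedSweep",
    "SimulatedExperiment",
    "open_probability",
    "ic50_at",
    "simulate_sweep",
    "simulate_experiment",
    "preset",
    "plane_wave_map",
    "PRESETS",
]


@dataclass
class GatingParams:
    """Biphasic SK2 gating parameters (concentrations uM, potentials mV)."""

    ec50_act: float = 0.46
    h_act: float = 2.6
    ic50_ref: float = 20.0
    v_ref: float = -40.0
    slope_mv: float = 17.0    # e-fold IC50 decrease per this much depolarization
    h_inh: float = 2.0
    g_total: float = 5.0      # lumped N*g, nS
    e_k: float = -83.7
    phospho_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ec50_act", "h_act", "ic50_ref", "slope_mv", "h_inh", "g_total"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.phospho_factor < 1:
            raise ValueError("phospho_factor must be >= 1")


def ic50_at(v: float, g: GatingParams) -> float:
    """Voltage-dependent inhibition midpoint (uM), including phospho relief."""
    return g.phospho_factor * g.ic50_ref * np.exp(-(v - g.v_ref) / g.slope_mv)


def open_probability(ca, v: float, g: GatingParams):
    """Biphasic open probability; vectorized over ``ca`` (uM, >= 0)."""
    ca = np.asarray(ca, float)
    if np.any(ca < 0):
        raise ValueError("ca must be >= 0")
    ic50 = ic50_at(v, g)
    with np.errstate(divide="ignore"):
        act = np.where(ca > 0,
                       ca ** g.h_act / (ca ** g.h_act + g.ec50_act ** g.h_act),
                       0.0)
    inh = 1.0 / (1.0 + (ca / ic50) ** g.h_inh)
    po = act * inh
    if po.ndim == 0:
        return float(po)
    return po


@dataclass
class TransientParams:
    """Phenomenological Ca2+ transient (uM / ms / mV)."""

    resting_ca: float = 0.1
    amp_peak: float = 0.6     # bell maximum of amp(V), uM
    v_center: float = 0.0     # bell centre, mV
    v_width: float = 50.0     # bell width, mV
    tau_rise: float = 15.0
    tau_decay: float = 200.0

    def __post_init__(self) -> None:
        if self.amp_peak < 0 or self.resting_ca < 0:
            raise ValueError("amplitudes must be >= 0")
        if not (self.tau_rise > 0 and self.tau_decay > 0):
            raise ValueError("taus must be > 0")

    def amplitude(self, v: float) -> float:
        """Bell-shaped peak-amplitude scale vs step potential."""
        return self.amp_peak * np.exp(-(((v - self.v_center) / self.v_width) ** 2))


def _transient(t_rel: np.ndarray, amp: float, tp: TransientParams):
    """Closed-form ca_i and d(ca_i)/dt for t_rel >= 0 (0 before onset)."""
    tr, td = tp.tau_rise, tp.tau_decay
    pos = t_rel > 0
    e_r = np.where(pos, np.exp(-np.clip(t_rel, 0, None) / tr), 1.0)
    e_d = np.where(pos, np.exp(-np.clip(t_rel, 0, None) / td), 1.0)
    u = (1.0 - e_r) ** 2
    ca = tp.resting_ca + np.where(pos, amp * u * e_d, 0.0)
    du = 2.0 * (1.0 - e_r) * e_r / tr
    dca = np.where(pos, amp * e_d * (du - u / td), 0.0)
    return ca, dca


@dataclass
class ICaParams:
    """Phenomenological L-type Ca2+ current surrogate (the residual)."""

    g_ca: float = 25.0        # nS
    e_ca: float = 60.0        # mV
    act_midpoint: float = -15.0
    act_slope: float = 6.0
    tau_inact: float = 30.0   # ms

    def __post_init__(self) -> None:
        if not self.tau_inact > 0:
            raise ValueError("tau_inact must be > 0")

    def activation(self, v: float) -> float:
        return 1.0 / (1.0 + np.exp(-(v - self.act_midpoint) / self.act_slope))


@dataclass
class NoiseParams:
    sigma_current: float = 5.0       # pA, additive Gaussian
    sigma_fluor_frac: float = 0.02   # multiplicative fractional
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_current < 0 or self.sigma_fluor_frac < 0:
            raise ValueError("noise sigmas must be >= 0")


#: simulation-wide geometry defaults
DT_CURRENT = 0.2     # ms (5 kHz digitization)
DT_FLUOR = 5.0       # ms (confocal line-scan rate)
GAMMA = 110.0        # ms, diffusion-lag constant shared with the reconstruction
DEFAULT_CAPACITANCE = 150.0  # pF, adult rat ventricular myocyte
DEFAULT_CALIBRATION = CalibrationParams(fmax=1000.0)


@dataclass
class GroundTruth:
    """Noise-free internal channels of one simulated sweep (current grid)."""

    t: np.ndarray
    ca_i: np.ndarray
    ca_sm: np.ndarray
    i_sk: np.ndarray
    i_ca: np.ndarray


@dataclass
class SimulatedSweep:
    sweep: Sweep
    truth: GroundTruth


def _ground_truth(
    t: np.ndarray,
    protocol: StepProtocol,
    tp: TransientParams,
    g: GatingParams,
    ica: ICaParams,
    with_sk: bool,
) -> GroundTruth:
    v_step = protocol.step_potential
    v_hold = protocol.holding_potential
    t_rel = t - protocol.step_onset
    in_step = (t >= protocol.step_onset) & (t <= protocol.step_end)
    v_of_t = np.where(in_step, v_step, v_hold)

    amp = tp.amplitude(v_step)
    ca_i, dca = _transient(t_rel, amp, tp)

    # submembrane truth: forward diffusion-lag up to its peak, then relaxation
    # to rest with the bulk decay constant
    fwd = ca_i + GAMMA * dca
    i_pk = int(np.argmax(fwd))
    ca_sm = fwd.copy()
    tail = np.arange(t.size) > i_pk
    ca_sm[tail] = tp.resting_ca + (fwd[i_pk] - tp.resting_ca) * np.exp(
        -(t[tail] - t[i_pk]) / tp.tau_decay
    )
    ca_sm = np.clip(ca_sm, 0.0, None)

    if with_sk:
        po = _po_path(ca_sm, v_of_t, g)
        i_sk = g.g_total * po * (v_of_t - g.e_k)
    else:
        i_sk = np.zeros_like(t)

    i_ca = np.where(
        in_step,
        ica.g_ca * ica.activation(v_step)
        * np.exp(-np.clip(t_rel, 0, None) / ica.tau_inact)
        * (v_step - ica.e_ca),
        0.0,
    )
    return GroundTruth(t=t, ca_i=ca_i, ca_sm=ca_sm, i_sk=i_sk, i_ca=i_ca)


def _po_path(ca_sm: np.ndarray, v_of_t: np.ndarray, g: GatingParams) -> np.ndarray:
    """Po along a (ca, V) path; vectorized over the two voltage levels."""
    po = np.empty_like(ca_sm)
    for v in np.unique(v_of_t):
        sel = v_of_t == v
        po[sel] = open_probability(ca_sm[sel], float(v), g)
    return po


def _sweep_seed(master_seed: int, cell_id: str, condition: str,
                voltage: float, phase: str) -> np.random.SeedSequence:
    """Stated seed-splitting rule: master entropy + a content-derived spawn key."""
    key = (
        zlib.crc32(cell_id.encode()),
        zlib.crc32(condition.encode()),
        int(round(voltage * 1000)) & 0xFFFFFFFF,
        zlib.crc32(phase.encode()),
    )
    return np.random.SeedSequence(entropy=master_seed, spawn_key=key)


def simulate_sweep(
    protocol: StepProtocol,
    tp: TransientParams | None = None,
    gating: GatingParams | None = None,
    ica: ICaParams | None = None,
    noise: NoiseParams | None = None,
    with_sk: bool = True,
    *,
    capacitance: float = DEFAULT_CAPACITANCE,
    calibration: CalibrationParams = DEFAULT_CALIBRATION,
    cell_id: str = "cell01",
    condition: str = "baseline",
    duration: float | None = None,
    dt_current: float = DT_CURRENT,
    dt_fluor: float = DT_FLUOR,
    rng: np.random.Generator | None = None,
) -> SimulatedSweep:
    """Synthesize one voltage-clamp sweep with its ground truth.

    The recorded current is I_SK (if ``with_sk``) + the L-type surrogate +
    additive Gaussian noise; the fluorescence trace is the inverse-calibrated
    bulk transient, sampled at the line-scan rate, with multiplicative noise.
    """
    tp = tp or TransientParams()
    gating = gating or GatingParams()
    ica = ica or ICaParams()
    noise = noise or NoiseParams()
    if rng is None:
        rng = np.random.default_rng(
            _sweep_seed(noise.seed, cell_id, condition,
                        protocol.step_potential, "sk" if with_sk else "nosk"))

    total = duration if duration is not None else protocol.step_end + 150.0
    n_cur = int(round(total / dt_current)) + 1
    t_cur = dt_current * np.arange(n_cur)
    truth = _ground_truth(t_cur, protocol, tp, gating, ica, with_sk)

    current = truth.i_sk + truth.i_ca
    if noise.sigma_current > 0:
        current = current + rng.normal(0.0, noise.sigma_current, current.shape)

    n_flu = int(np.floor(total / dt_fluor)) + 1
    t_flu = dt_fluor * np.arange(n_flu)
    amp = tp.amplitude(protocol.step_potential)
    ca_flu, _ = _transient(t_flu - protocol.step_onset, amp, tp)
    f = inverse_calibrate(TimeSeries(0.0, dt_fluor, ca_flu, "uM"), calibration)
    fvals = f.values
    if noise.sigma_fluor_frac > 0:
        fvals = fvals * (1.0 + rng.normal(0.0, noise.sigma_fluor_frac, fvals.shape))
        # multiplicative noise can nudge a sample to/above Fmax; keep it physical
        fvals = np.clip(fvals, 1e-9, calibration.fmax * (1 - 1e-9))

    sweep = Sweep(
        current=TimeSeries(0.0, dt_current, current, "pA"),
        fluorescence=TimeSeries(0.0, dt_fluor, fvals, "a.u."),
        protocol=protocol,
        capacitance=capacitance,
        condition=condition,
        cell_id=cell_id,
        fmax=calibration.fmax,
    )
    return SimulatedSweep(sweep=sweep, truth=truth)


# ---------------------------------------------------------------------------
# condition presets and full experiments
# ---------------------------------------------------------------------------

#: condition modifiers: (phospho_factor, transient amplitude scale, g_ca scale)
CONDITION_EFFECTS = {
    "baseline": (1.0, 1.0, 1.0),
    "ISO": (5.0, 1.5, 1.5),      # PKA relief of inhibition + larger I_Ca/transient
    "PKI": (1.0, 1.0, 1.0),      # PKA blocked: no relief regardless of ISO
}

#: named parameter bundles (cell models)
PRESETS = {
    # pressure-overload myocyte: appreciable SK conductance
    "tab-baseline": dict(gating=GatingParams(), transient=TransientParams(),
                         ica=ICaParams(), holding=-40.0),
    # healthy myocyte: SK conductance functionally dormant (small g_total)
    "sham-baseline": dict(gating=GatingParams(g_total=0.5),
                          transient=TransientParams(), ica=ICaParams(),
                          holding=-40.0),
    # cultured myocyte overexpressing rSK2: large conductance, slower transient
    "overexpress": dict(gating=GatingParams(g_total=15.0),
                        transient=TransientParams(tau_decay=250.0),
                        ica=ICaParams(), holding=-45.0),
}


def preset(name: str) -> dict:
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; options: {sorted(PRESETS)}")
    return {k: (replace(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in base.items()}


@dataclass
class SimulatedExperiment:
    experiment: ExperimentSet
    truths: dict[tuple[str, str, float], GroundTruth]


def apply_condition(
    condition: str,
    gating: GatingParams,
    tp: TransientParams,
    ica: ICaParams,
) -> tuple[GatingParams, TransientParams, ICaParams]:
    """Return parameter bundles modified by a pharmacological condition tag."""
    base = condition.split("+")[0]
    pf, amp_scale, gca_scale = CONDITION_EFFECTS.get(base, (1.0, 1.0, 1.0))
    return (
        replace(gating, phospho_factor=gating.phospho_factor * pf),
        replace(tp, amp_peak=tp.amp_peak * amp_scale),
        replace(ica, g_ca=ica.g_ca * gca_scale),
    )


def simulate_experiment(
    voltages,
    conditions=("baseline",),
    *,
    seed: int = 0,
    preset_name: str = "tab-baseline",
    noise: NoiseParams | None = None,
    blocker: str = "APA",
    n_cells: int = 1,
    step_onset: float = 50.0,
    step_duration: float = 300.0,
    gating: GatingParams | None = None,
    transient: TransientParams | None = None,
    ica: ICaParams | None = None,
) -> SimulatedExperiment:
    """Build a full pre/post-blocker experiment across voltages and conditions.

    For each (cell, condition, voltage) two sweeps are produced: the
    pre-blocker recording (SK present) and the post-blocker recording (SK
    removed, condition tagged ``<condition>+<blocker>``), each with a fresh
    derived seed.  Ground truths are keyed by (cell_id, condition, voltage).
    """
    voltages = list(voltages)
    if any(v < -80 or v > 60 for v in voltages):
        raise ValueError("voltages must lie within [-80, +60] mV")
    bundle = preset(preset_name)
    g0 = gating if gating is not None else bundle["gating"]
    tp0 = transient if transient is not None else bundle["transient"]
    ica0 = ica if ica is not None else bundle["ica"]
    holding = bundle["holding"]
    noise = noise or NoiseParams(seed=seed)
    noise = replace(noise, seed=seed)

    sweeps: list[Sweep] = []
    truths: dict[tuple[str, str, float], GroundTruth] = {}
    for ci in range(n_cells):
        cell_id = f"cell{ci + 1:02d}"
        for cond in conditions:
            g, tp, ic = apply_condition(cond, g0, tp0, ica0)
            for v in voltages:
                protocol = StepProtocol(
                    holding_potential=holding, step_potential=float(v),
                    step_onset=step_onset, step_duration=step_duration)
                pre = simulate_sweep(
                    protocol, tp, g, ic, noise, with_sk=True,
                    cell_id=cell_id, condition=cond)
                post = simulate_sweep(
                    protocol, tp, g, ic, noise, with_sk=False,
                    cell_id=cell_id, condition=f"{cond}+{blocker}")
                sweeps.extend([pre.sweep, post.sweep])
                truths[(cell_id, cond, float(v))] = pre.truth
    return SimulatedExperiment(experiment=ExperimentSet(sweeps), truths=truths)


# ---------------------------------------------------------------------------
# synthetic optical-map movies
# ---------------------------------------------------------------------------

def plane_wave_map(
    n_frames: int = 400,
    shape: tuple[int, int] = (24, 24),
    frame_interval: float = 0.5,
    pixel_pitch: float = 0.15,
    cv_cm_s: float = 60.0,
    angle_deg: float = 0.0,
    t_first: float = 10.0,
    apd_tau: float = 50.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    polarity: str = "up",
):
    """Synthetic planar-wavefront AP movie with exponential repolarization.

    Each pixel fires at t_act = t_first + distance-along-wavefront / speed,
    rising instantly to ``amplitude`` and repolarizing as exp(-t/apd_tau), so
    APD at level L is apd_tau * ln(100 / (100 - L)) exactly.  Returns a
    :class:`~cardiosk.map_metrics.VoltageMap`.
    """
    from .map_metrics import VoltageMap

    rows, cols = shape
    speed_mm_ms = cv_cm_s / 100.0
    theta = np.deg2rad(angle_deg)
    x = np.arange(cols) * pixel_pitch
    y = np.arange(rows) * pixel_pitch
    X, Y = np.meshgrid(x, y)
    t_act = t_first + (X * np.cos(theta) + Y * np.sin(theta)) / speed_mm_ms
    t = frame_interval * np.arange(n_frames)
    rel = t[:, None, None] - t_act[None, :, :]
    frames = np.where(rel >= 0, amplitude * np.exp(-np.clip(rel, 0, None) / apd_tau), 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
    if polarity == "down":
        frames = -frames
    return VoltageMap(frames, frame_interval, pixel_pitch, polarity=polarity)
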