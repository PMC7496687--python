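# Methods

`cardiosk` analyses the small-conductance Ca²⁺-activated K⁺ (SK) current of
ventricular myocytes and ships a mechanistic simulator so that every analysis
stage can be validated end-to-end without recordings. This note documents the
models, the estimator choices, and what the synthetic data does and does not
emulate.

## Fluorescence calibration

Single-wavelength Rhod-2 fluorescence is converted to bulk calcium with the
pseudo-ratio equation

    [Ca²⁺]ᵢ = K_d · (F − F_min) / (F_max − F)

with K_d = 1.58 µM and F_min = F_max/15. F_max is a per-cell constant
(pipette rupture into 1 mM Ca²⁺ bath); when the baseline drifts, F/F₀
replaces F with F_max expressed on the same scale (`mode="F_over_F0"` — the
arithmetic is identical, the tag documents the scale). Samples at or above
F_max are rejected (the equation diverges); samples below F_min are clipped
to 0 µM with a logged count, since negative concentrations can only be noise.
The algebraic inverse maps [0, ∞) µM onto [F_min, F_max) and is what the
simulator uses to synthesize dye signals; calibration and inverse are mutual
inverses to better than 1e-9 relative.

## Submembrane Ca²⁺ reconstruction

SK channels sit in the sarcolemma outside the dyadic cleft and sense a
concentration that leads the bulk transient. The submembrane estimate is the
diffusion-lag forward formula

    [Ca²⁺]_sm(t) = [Ca²⁺]ᵢ(t) + γ · d[Ca²⁺]ᵢ/dt,   γ = 110 ms,

computed as: Savitzky–Golay smoothing (5-point window, polynomial order 2 —
the order is not dictated by the acquisition convention, so it is exposed as
a parameter; 2 is the common default for 5-point windows), central-difference
derivative of the smoothed trace (one-sided at the edges), γ-term added to
the raw bulk trace. Whether the derivative should be taken on the smoothed
or raw trace is ambiguous; we smooth first and document it.

The forward formula is only trusted through the rising phase and peak: its
decay tail both amplifies noise and systematically understates the
submembrane concentration relative to its peak. Past the peak the estimate
is therefore continued as a single exponential with the **tau and baseline of
the bulk-decay fit** (a least-squares single exponential from the bulk peak),
anchored at the forward-estimate peak. Numerical choices that matter:

- the peak is located and read on the SG-smoothed forward estimate — the raw
  single-sample maximum inherits the full γ-amplified derivative noise and is
  an upward-biased anchor (extreme-value selection);
- a flat input trace is passed through unchanged (the γ-term vanishes and
  there is no decay to splice); a trace whose bulk signal peaks at the end
  has no decay phase and is an error;
- negative reconstructed samples are clipped to 0 with a logged count.

## Blocker-subtraction current isolation

I_SK is operationally the apamin- (or UCL-1684-) sensitive current:
pre-blocker minus post-blocker trace of the same cell and step. No filtering
or temporal realignment is applied — protocol timing must match exactly so
that misalignment fails loudly instead of creating subtraction artefacts.
The post-blocker trace is kept as the residual (L-type Ca²⁺ current plus
leak; leak is not modelled separately). Pairing is by condition tag:
`ISO+APA` pairs with `ISO`, `APA` with `baseline`. I–V summaries report, per
voltage, the peak outward I_SK density and peak inward residual magnitude
(pA/pF) and the peak calibrated [Ca²⁺], pooled over cells as mean ± SD.

Peak *times* use a first-attainment rule: the reported time is the first
sample within 0.5% of the extremum (span-relative; exact ties break
earliest). This matters because a biphasically gated current crosses its
optimal Ca²⁺ twice — on the transient rise and again on the decay — with
near-identical amplitudes under instantaneous gating, and which discrete
sample wins by a fraction of a percent is arbitrary. Peak *amplitudes* are
always the true extremum.

## In-situ Ca²⁺-sensitivity assay

The decaying phase of a depolarization-evoked transient is used as a slow
monotone [Ca²⁺] ramp. From the I_SK peak to the end of the step, each
current sample is paired with the simultaneous reconstructed [Ca²⁺]_sm
sample; non-monotone jitter is handled by dropping any sample whose [Ca²⁺]
is not strictly below the lowest kept so far (cleanup, not smoothing — the
measured pairing is preserved). The pairs are fitted, unweighted and in
linear concentration space, with the activation Hill equation

    I/I_max = 1 / (1 + (EC50/[Ca²⁺])^h)

multistarted over EC50 ∈ {0.2, 0.5, 1.0} µM × h ∈ {1, 2, 4}. The inhibition
arm is deliberately excluded from this model: the assay is valid only where
inhibition has relaxed (see below). I_max is by convention the peak I_SK of
the same cell under β-adrenergic stimulation — the least inhibited, hence
most nearly saturated, current; when absent the sweep's own peak is used and
flagged. The fit requires ≥ 8 points spanning ≥ 3-fold in [Ca²⁺]; an EC50
outside [1e-3, 1e3] µM is flagged unreliable. The ramp is truncated at the
end of the step (the low end is otherwise noise-floor dependent); no
baseline subtraction is applied to I before normalization.

Before pairing, the isolated current is **block-averaged onto the line-scan
grid** (mean over each 5 ms bin). This is an explicit down-sampling step
with two purposes: it puts current and calcium on a common time base, and it
suppresses the wide-band noise that subtraction doubles. Taking I_max as the
raw maximum over thousands of 5 kHz samples would otherwise carry a
systematic extreme-value bias of several percent that propagates into a
flattened Hill coefficient.

### Assay operating point

The end-to-end validation (`cardiosk.assay.run_ramp_assay`) simulates a
cultured SK2-overexpressing cell (holding −45 mV) at a step of **−22 mV**
with a 500 ms step. The operating point is set by a validity requirement:
the ramp must span at least a 3-fold [Ca²⁺] range around the activation EC50
while the local inhibition IC50 stays well above the ramp top. At more
positive steps the voltage-dependent inhibition midpoint falls into the ramp
range (at +5 mV the ramp does not even span 3-fold under this model) and no
activation-only fit can be unbiased there; at more negative steps the small
transient leaves the ramp top too far below saturation for the I_max
normalization to anchor. With the defaults the noiseless pipeline recovers
the generating EC50 = 0.46 µM and h = 2.6 to ≲ 0.5%, and at 2% fluorescence
noise plus 15 pA current noise the medians over 100 seeds are within ~3%.

The inhibition arm is validated separately: fitting
Po = A/(1 + ([Ca²⁺]/IC50)^h) to the descending limb of the model's
open-probability curve at the reference voltage recovers the generating
IC50 of 20 µM.

## Biphasic gating model

Open probability is a product of calmodulin-mediated activation and
voltage-dependent Ca²⁺ inhibition:

    Po(ca, V) = [ca^h_act / (ca^h_act + EC50^h_act)]
              · [1 / (1 + (ca/IC50(V))^h_inh)]
    IC50(V)   = phospho_factor · IC50_ref · exp(−(V − V_ref)/s)

Defaults: EC50 = 0.46 µM, h_act = 2.6 (the in-situ estimates), IC50_ref =
20 µM at V_ref = −40 mV, h_inh = 2, slope s = 17 mV per e-fold. Gating is
instantaneous — SK kinetics are fast relative to the transient. The
functional form and slope of the inhibition's voltage dependence are model
assumptions (only "voltage-dependent, IC50 ≈ 20 µM" is constrained by
experiment): the exponential form is the simplest monotone choice and the
slope is set so that by +30…+40 mV the IC50 falls into the activation range,
which is what makes the current nearly vanish at +30 mV despite an
undiminished Ca²⁺ transient. With a much shallower slope (e.g. 40 mV per
e-fold) the inhibition never suppresses the Po optimum at positive voltages
and no rectification emerges; 17 mV per e-fold reproduces the observed
I–V shape (peak near −10 mV, +40 mV density ~15% of maximum).

Phosphorylation (PKA at S465, or the S465D phosphomimetic) is modelled
purely as multiplicative relief of inhibition — `phospho_factor` scales
IC50_ref and never touches the activation arm. This encodes the mechanistic
finding that β-adrenergic stimulation enhances the current without changing
its sensitivity to activating submicromolar Ca²⁺.

## Synthetic data generator

One simulated sweep contains:

- **Ca²⁺ transient**: ca(t′) = rest + amp(V)·(1 − e^(−t′/τ_rise))²·e^(−t′/τ_decay),
  rest 0.1 µM, τ_rise 15 ms, τ_decay 200 ms (250 ms for the cultured-cell
  preset), with amp(V) a bell centred at 0 mV (width 50 mV, maximum 0.6 µM)
  mimicking the L-type current's voltage dependence. The squared rise gives
  the transient a sigmoidal foot; a kinked onset would make the
  derivative-boosted submembrane signal peak instantaneously at the step
  edge, destroying the current-before-calcium timing order.
- **Submembrane truth**: the forward diffusion-lag formula up to its peak,
  then relaxation to rest with the bulk decay constant — the same
  submembrane model the reconstruction estimates, so estimator error is
  attributable to the estimator. The pure forward formula's tail
  (scaled by 1 − γ/τ_decay) is not used as truth: no single-exponential
  continuation can represent it, and the submembrane pool is expected to
  re-equilibrate toward the bulk once release stops.
- **I_SK**: g_total · Po(ca_sm, V) · (V − E_K), E_K = −83.7 mV from the
  5.4/140 mM K⁺ gradient; g_total 5 nS (pressure-overload preset), 0.5 nS
  (healthy "dormant" preset), 15 nS (overexpression preset).
- **Residual current**: L-type surrogate g_ca·act(V)·e^(−t′/τ_inact)·(V−E_Ca)
  with Boltzmann activation (midpoint −15 mV, slope 6 mV), τ_inact 30 ms,
  E_Ca +60 mV, g_ca 25 nS (≈ −10 pA/pF peak at 150 pF).
- **Noise**: additive Gaussian on the current (default 5 pA RMS) and
  multiplicative Gaussian on the fluorescence (default 2%); fluorescence is
  clipped below F_max to stay physical.

Currents are digitized at 5 kHz (0.2 ms), fluorescence at the 5 ms line-scan
rate, holding −40 mV (−45 mV for the overexpression preset), steps of 300 ms
(500 ms in the ramp assay) from 50 ms onset. Condition tags modify
parameters: `ISO` sets phospho_factor 5 and scales transient amplitude and
g_ca by 1.5; `PKI` pins phospho_factor at 1. Every sweep derives its RNG
from `SeedSequence(master, spawn_key=(crc32(cell), crc32(condition),
voltage, crc32(phase)))`, so experiments are reproducible sweep-by-sweep and
pre/post sweeps have independent noise.

What the generator does **not** emulate: SR release flux and its
restitution, NCX and other background currents, dyadic [Ca²⁺] (the SK
channels sense the submembrane pool, consistent with their location outside
the dyad), rundown, series-resistance and junction-potential errors,
kinetic (non-instantaneous) gating, and motion or photobleaching artefacts
in the dye signal. Its transient timescales are faster than real cultured
myocyte data (submembrane time-to-peak ~10 ms rather than tens of ms), so
timing checks assert only orderings, never absolute latencies. Passing tests
therefore demonstrate estimator correctness under the stated model, not
robustness to every pathology of real recordings.

## Optical-map metrics

Per-pixel activation is the time of maximum dF/dt (central differences,
earliest on ties) in the beat window; AP duration at level L (75 or 90%) is
the first post-peak crossing of peak − L%·amplitude, located with sub-frame
linear interpolation (0.5 ms frames would otherwise quantize APD), measured
from the activation time. Amplitude is peak minus the pre-upstroke baseline
(median of samples before activation). Pixels are masked when the AP
amplitude is below 5× the pre-upstroke baseline SD (the mask rule is a
package choice; no standard exists). Di-4-ANEPPS signals declare
`polarity="down"` and are negated. Conduction velocity is a single global
plane fit a + bx + cy to the activation map over unmasked pixels;
CV = 1/‖(b, c)‖ (mm/ms → cm/s); a plane-fit RMSE above 2 ms flags a
non-planar (radial/colliding) wavefront instead of silently reporting a
speed. An optional 3×3 spatial mean filter is off by default. Local vector
fields, phase mapping and motion correction are out of scope.

## Free-ion solver

Pipette recipes quote totals; the solver returns free concentrations after
1:1 mass-action equilibration of cations (Mg²⁺, Ca²⁺) with ligands (ATP,
GTP, EGTA, indicator). Proton competition and higher complexes (MgHATP…)
are folded into *apparent* association constants at the stated pH — the
classic chelator-calculator simplification. The shipped defaults at pH 7.2,
22 °C, I ≈ 0.15 M: nucleotides log K ≈ 4.0 reduced by terminal-phosphate
protonation (pKa₂ 6.95); EGTA log K 10.86 (Ca) / 5.21 (Mg) reduced by the
amine protonations (pKa 9.40, 8.79); Rhod-2 at its calibration K_d of
1.58 µM for Ca²⁺ and a weak approximate 10² M⁻¹ for Mg²⁺. Every constant
carries a provenance note and can be overridden; no ionic-strength or
temperature extrapolation is attempted. The solver is a damped fixed-point
iteration on the free cation vector, run to a mass-conservation residual of
1e-12 mM (error after 10⁴ iterations), verified against a brute-force
bisection oracle on all one-cation/one-ligand cases. For the recording
pipette mix (6 Mg / 5 ATP / 0.1 GTP / 0.1 Rhod-2, pH 7.2) it yields
1.35 mM free Mg²⁺; the value quoted with the recipe is 1.37 mM, and
agreement to the second decimal would require the exact constant set of the
original calculator.

## Problem sizes

All validation runs are desk-scale by construction: sweeps are 0.5–0.7 s at
5 kHz (≈ 3500 samples), experiments are ≤ 9 voltages × 2 conditions × 2
sweeps, the noisy-recovery study uses 100 seeds, and synthetic optical maps
are 24–40 px square × 400–600 frames. The full test suite runs in well
under a minute on one CPU.
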