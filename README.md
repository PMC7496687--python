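# cardiosk

Analysis of small-conductance Ca²⁺-activated K⁺ (SK) currents in ventricular
myocytes, for cellular electrophysiologists working with simultaneous
patch-clamp / confocal Ca²⁺ recordings and ex-vivo optical mapping.

SK2 channels are gated by submembrane Ca²⁺ in a **biphasic** way: activated
by submicromolar Ca²⁺ through constitutively bound calmodulin
(EC50 ≈ 0.46 µM, Hill coefficient h ≈ 2.6) and inhibited by
tens-of-micromolar Ca²⁺ in a voltage-dependent manner (IC50 ≈ 20 µM at
−40 mV, falling e-fold per ~17 mV of depolarization). The product

    Po(ca, V) = ca^h / (ca^h + EC50^h) · 1 / (1 + (ca/IC50(V))²)
    I_SK      = g · Po([Ca²⁺]_sm, V) · (V − E_K)

rectifies: peak current density declines at positive potentials despite
rising Ca²⁺ transients. PKA phosphorylation relieves the inhibition
(modelled as a multiplicative factor on IC50) without changing the
activation EC50 — which is why β-adrenergic stimulation recruits the current.

The package covers the full analysis chain around that model:

- `cardiosk.io_model` — sweep/experiment data model; diff-able CSV + JSON
  experiment format; alignment helpers (`resample`, `block_average`)
- `cardiosk.calcium` — Rhod-2 pseudo-ratio calibration
  ([Ca²⁺]ᵢ = K_d(F−F_min)/(F_max−F), K_d = 1.58 µM, F_min = F_max/15) and
  submembrane reconstruction [Ca²⁺]_sm = [Ca²⁺]ᵢ + γ·d[Ca²⁺]ᵢ/dt (γ = 110 ms,
  Savitzky–Golay smoothed derivative, exponential decay continuation)
- `cardiosk.isk` — apamin/UCL-subtraction isolation of I_SK, peak extraction,
  pooled I–V / peak-Ca–V summaries, rundown normalization
- `cardiosk.sensitivity` — in-situ Hill fit of I/I_max vs the decaying Ca²⁺
  ramp; inhibition-arm fit; biphasic timing metrics
- `cardiosk.map_metrics` — optical-map activation (max dF/dt), APD75/APD90
  with sub-frame interpolation, plane-fit conduction velocity
- `cardiosk.simulate` — the biphasic gating model plus a full synthetic
  voltage-clamp experiment generator (paired pre/post-blocker sweeps with
  ground truth) and synthetic optical-map movies
- `cardiosk.solutions` — Maxchelator-style free-ion solver for pipette
  recipes (apparent-constant mass action)
- `cardiosk.assay` — the end-to-end sensitivity assay on synthetic data

## Worked example

`examples/03_hill_sensitivity.py` runs the whole chain — simulate a cultured
SK2-overexpressing cell before/after blocker under baseline and ISO,
calibrate the dye signal, reconstruct submembrane Ca²⁺, isolate I_SK by
subtraction, pair the post-peak current with the decaying Ca²⁺ ramp and fit
the Hill equation:

```
generating parameters: EC50 = 0.46 uM, h = 2.6
baseline ramp fit:     EC50 = 0.480 uM, h = 2.57  (rmse 0.0132, n = 89)
ISO ramp fit:          EC50 = 0.425 uM, h = 2.69
timing (baseline sweep): I_SK peaks 12.0 ms after onset, [Ca2+]_sm 14.6 ms
```

Under realistic noise the estimator recovers the generating activation
parameters to a few percent, the β-adrenergic condition leaves the fitted
EC50 essentially unchanged (inhibition relief, not sensitization), and the
current peaks while submembrane Ca²⁺ is still rising — the biphasic
signature. The other examples cover calibration/reconstruction (`01`), I–V
assembly and rectification relief (`02`), optical-map APD/CV (`04`) and the
pipette free-Mg²⁺ computation (`05`, printing 1.35 mM free of 6 mM total).

See `docs/methods.md` for the model details, estimator choices and the
limits of what the synthetic data emulates.

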