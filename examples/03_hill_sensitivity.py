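"""In-situ Ca2+ sensitivity: fit the Hill equation to a transient decay ramp.

Runs the full assay — simulate a cell before/after blocker under baseline and
ISO, isolate I_SK, reconstruct submembrane Ca2+, pair the post-peak current
with the decaying Ca2+ ramp, and fit I/Imax = 1/(1 + (EC50/[Ca])^h) — then
compares the fitted activation parameters with the generating ones.
"""

from cardiosk.assay import run_ramp_assay
from cardiosk.simulate import NoiseParams

result = run_ramp_assay(seed=3, noise=NoiseParams(sigma_current=15.0,
                                                  sigma_fluor_frac=0.02, seed=3))

print("generating parameters: EC50 = "
      f"{result.true_ec50:.2f} uM, h = {result.true_h:.1f}")
print(f"baseline ramp fit:     EC50 = {result.fit.ec50:.3f} uM, "
      f"h = {result.fit.h:.2f}  (rmse {result.fit.rmse:.4f}, "
      f"n = {result.fit.n_points})")
print(f"ISO ramp fit:          EC50 = {result.fit_iso.ec50:.3f} uM, "
      f"h = {result.fit_iso.h:.2f}")
print()
print("PKA-style relief of inhibition raises the current amplitude but leaves")
print("the fitted activation EC50 essentially unchanged — phosphorylation does")
print("not alter the channel's affinity for activating submicromolar Ca2+.")
print()
print(f"timing (baseline sweep): I_SK peaks {result.timing.ttp_isk:.1f} ms "
      f"after onset, [Ca2+]_sm {result.timing.ttp_casm:.1f} ms — the current")
print("peaks while submembrane Ca2+ is still rising (biphasic gating).")
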