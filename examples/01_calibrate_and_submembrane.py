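"""Calibrate a Rhod-2 trace and reconstruct submembrane Ca2+.

Builds a synthetic fluorescence transient (a voltage-clamp sweep at -10 mV),
converts it to bulk [Ca2+]_i with the pseudo-ratio equation, and adds the
diffusion-lag derivative term to estimate the submembrane concentration the
SK channels actually sense.
"""

import numpy as np

from cardiosk.calcium import (CalibrationParams, calibrate_fluorescence,
                              reconstruct_submembrane)
from cardiosk.io_model import StepProtocol
from cardiosk.simulate import NoiseParams, preset, simulate_sweep

bundle = preset("tab-baseline")
protocol = StepProtocol(holding_potential=-40.0, step_potential=-10.0,
                        step_onset=50.0, step_duration=300.0)
sweep = simulate_sweep(protocol, bundle["transient"], bundle["gating"],
                       bundle["ica"], NoiseParams(2.0, 0.01, seed=4)).sweep

ca_i = calibrate_fluorescence(sweep.fluorescence,
                              CalibrationParams(fmax=sweep.fmax))
traces = reconstruct_submembrane(ca_i)

print(f"bulk [Ca2+]_i:   rest {ca_i.values[:8].mean():.3f} uM, "
      f"peak {ca_i.values.max():.3f} uM at t = {ca_i.t[np.argmax(ca_i.values)]:.0f} ms")
print(f"submembrane:     peak {traces.ca_sm.values.max():.3f} uM at "
      f"t = {traces.ca_sm.t[np.argmax(traces.ca_sm.values)]:.0f} ms")
print(f"bulk decay fit:  tau {traces.decay_fit.tau:.0f} ms, "
      f"baseline {traces.decay_fit.baseline:.3f} uM")
print()
print("The derivative term makes the submembrane estimate peak higher and")
print("tens of ms earlier than the bulk transient; its decay follows the")
print("bulk decay time constant.")
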