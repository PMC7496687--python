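"""Optical-map analysis: APD map and conduction velocity of a paced wavefront.

Generates a synthetic planar-wavefront movie (60 cm/s at 30 degrees, 0.5 ms
frames, 0.15 mm pixels, exponential repolarization with tau = 50 ms), builds
the per-pixel activation/APD75 maps and recovers the conduction velocity by a
global plane fit.
"""

import numpy as np

from cardiosk.map_metrics import build_apd_map, conduction_velocity
from cardiosk.simulate import plane_wave_map

vm = plane_wave_map(n_frames=400, shape=(40, 40), cv_cm_s=60.0,
                    angle_deg=30.0, apd_tau=50.0, noise_sd=0.01, seed=8)
maps = build_apd_map(vm, level=75.0)
cv = conduction_velocity(maps.activation, maps.mask, vm.pixel_pitch)

apd_true = 50.0 * np.log(4.0)  # exponential repolarization closed form
print(f"analyzable pixels: {maps.mask.sum()} / {maps.mask.size}")
print(f"APD75: {np.mean(maps.apd[maps.mask]):.2f} +/- "
      f"{np.std(maps.apd[maps.mask]):.2f} ms "
      f"(closed form {apd_true:.2f} ms)")
print(f"conduction velocity: {cv.cv:.1f} cm/s (generated 60.0), "
      f"plane-fit rmse {cv.rmse:.3f} ms, single wavefront: {cv.plane_ok}")
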