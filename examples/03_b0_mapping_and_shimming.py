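"""Dual-echo B0 mapping and volume-selective shimming of the heart phantom.

The heart phantom carries a smooth macroscopic background field (several
hundred Hz peak-to-peak over the heart) plus a localized ~20 Hz/mm gradient
at the inferior/inferolateral epicardial border. A field map is computed
from the phase images of the first two echoes (2.04 / 3.06 ms), then a
linear + second-order shim is fitted over the heart ROI and subtracted:
the macroscopic background collapses, leaving only the local epicardial
gradient.
"""

import numpy as np

from cardiot2star import (FieldMap, acquire, compute_b0_map, field_stats,
                          fit_shim, make_heart_phantom, protocol_preset)

heart = make_heart_phantom()
roi = np.hypot(*heart.geometry.coordinate_grids()) <= 35.0

# acquire the single-phase interleaved protocol and map B0 from its phases
series = acquire(heart.frame(0), protocol_preset("MS"))
phase = series.phase()
fmap = compute_b0_map(phase[0, 0, 0], phase[0, 0, 1],
                      series.te_ms[0], series.te_ms[1],
                      geometry=heart.geometry, mask=roi)
print(f"dual-echo field map: dTE = {fmap.dte_ms:.2f} ms, "
      f"unambiguous range +-{fmap.nyquist_hz:.0f} Hz")

pre = field_stats(fmap, roi)
print(f"before shim: peak-to-peak {pre['peak_to_peak_hz']:6.1f} Hz, "
      f"FWHM {pre['fwhm_hz']:5.1f} Hz, "
      f"max gradient {pre['max_gradient_hz_per_mm']:.1f} Hz/mm")

for order in (1, 2):
    sol = fit_shim(fmap, roi, order=order)
    post = field_stats(sol.shimmed_map, roi)
    print(f"order-{order} shim: peak-to-peak {post['peak_to_peak_hz']:6.1f} Hz, "
          f"FWHM {post['fwhm_hz']:5.1f} Hz "
          f"(reduction x{pre['peak_to_peak_hz'] / post['peak_to_peak_hz']:.1f})")
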