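"""Map T2* of the iron-doped cylinder with the interleaved multi-shot protocol.

Builds the 20 ms medium-T2* phantom, acquires the 9-echo MS protocol
(three excitations, 1.02 ms effective echo spacing) with mild noise, fits
the mono-exponential decay voxelwise and reports the ROI mean: the
recovered value should sit at the configured 20 ms ground truth.
"""

import numpy as np

from cardiot2star import (ImageGeometry, acquire, make_medium_t2star_phantom,
                          map_fit, protocol_preset, roi_mean_t2star,
                          scan_duration)

geometry = ImageGeometry(matrix=(128, 128), fov_mm=(144.0, 144.0),
                         slice_thickness_mm=8.0)
tissue = make_medium_t2star_phantom(geometry=geometry)
protocol = protocol_preset("MS")

series = acquire(tissue, protocol, noise_sigma=0.005, seed=1)
t2map = map_fit(series, tissue.object_mask())[0]
mean, std, n = roi_mean_t2star(t2map)

print(f"protocol: {protocol.strategy}, {protocol.n_echoes} echoes, "
      f"TE {protocol.te_ms[0]:.2f}..{protocol.te_ms[-1]:.2f} ms")
print(f"scan duration at 240 lines: {float(scan_duration(protocol, 240)):.0f} s")
print(f"ROI mean T2* = {mean:.2f} +- {std:.2f} ms over {n} voxels "
      f"(ground truth 20.00 ms)")
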