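"""Compare all five acquisition strategies on a static phantom.

On a motionless object the segmented k-space ordering is irrelevant, so the
single-phase (ME, MS), CINE (ME CINE, MS CINE) and multi-breath-hold
(MB CINE) strategies must deliver the same T2* map; the table printed below
shows ROI means agreeing to well under 0.5 ms, alongside each protocol's
scan-duration and acquisition-window bookkeeping.
"""

import numpy as np

from cardiot2star import (ImageGeometry, acquire, acquisition_window,
                          make_medium_t2star_phantom, map_fit, protocol_preset,
                          roi_mean_t2star, scan_duration)

geometry = ImageGeometry(matrix=(128, 128), fov_mm=(144.0, 144.0),
                         slice_thickness_mm=8.0)
tissue = make_medium_t2star_phantom(geometry=geometry)
roi = np.hypot(*geometry.coordinate_grids()) <= 30.0

print(f"{'strategy':9s} {'scan @240 lines':>15s} {'window':>8s} {'ROI T2* [ms]':>14s}")
for name in ("ME", "MS", "MB_CINE", "ME_CINE", "MS_CINE"):
    kwargs = {"n_phases": 3} if "CINE" in name else {}
    protocol = protocol_preset(name, **kwargs)
    series = acquire(tissue, protocol, noise_sigma=0.005, seed=7)
    t2map = map_fit(series, tissue.object_mask())[0]
    mean, std, _ = roi_mean_t2star(t2map, roi)
    sd = scan_duration(protocol, 240)
    dur = f"{sd.n_holds}x{sd.per_hold_s:.0f}s" if sd.n_holds > 1 else f"{sd.total_s:.0f}s"
    print(f"{name:9s} {dur:>15s} {acquisition_window(protocol):6.0f}ms "
          f"{mean:8.2f} +- {std:.2f}")
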