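"""CINE T2* mapping of the beating heart phantom, segment by segment.

Runs the full multi-breath-hold CINE chain: the dynamic heart phantom
(segment-specific T2* with a 27 % cyclic modulation, minimum in systole),
echoes interleaved over three misaligned breath-holds, landmark-based
affine registration, voxelwise fitting at every cardiac phase, and
six-sector segmental statistics. The printed table compares each segment's
recovered cycle modulation with the generator's ground truth, followed by
the paired end-diastole vs end-systole t-test.
"""

import numpy as np

from cardiot2star import RunConfig, paired_comparison, run_pipeline

sigma = np.exp(-2.04 / 14.0) / 50.0  # SNR ~ 50 at the first myocardial echo
config = RunConfig(phantom={"kind": "heart"},
                   protocol={"name": "MB_CINE"},
                   noise_sigma=float(sigma), seed=11,
                   outdir="scratch/example04")
bundle = run_pipeline(config)

truth = bundle.tissue.meta["segment_t2star_by_frame"]
pct_true = 100 * (truth.max(axis=0) - truth.min(axis=0)) / truth.min(axis=0)
summary = bundle.report.summary

print(f"{'segment':14s} {'ED [ms]':>8s} {'ES [ms]':>8s} {'cycle rise':>11s} {'truth':>7s}")
for row, pt in zip(summary.itertuples(), pct_true):
    print(f"{row.segment:2d} {row.name:11s} {row.end_diastole_ms:8.2f} "
          f"{row.end_systole_ms:8.2f} {row.percent_increase:10.1f}% {pt:6.1f}%")

test = paired_comparison(summary["end_diastole_ms"], summary["end_systole_ms"])
print(f"\npaired t-test ED vs ES over segments: t = {test['t']:.2f}, "
      f"p = {test['p']:.4f}")
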