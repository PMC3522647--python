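# cardiot2star

Simulation and analysis of **cardiac-triggered multi-echo gradient-echo T2\*
mapping**, aimed at quantitative-MRI researchers who want to study — on
controlled digital phantoms — how acquisition strategy, static-field (B0)
inhomogeneity, slice thickness and cardiac motion shape myocardial T2\*
estimates at ultrahigh field.

The package provides, as a plain Python library:

* **digital phantoms**: a long-T2\* agarose cylinder with an air capillary
  (dipole field perturbation) and water tube; a medium-T2\* iron-doped
  cylinder (T2\* = 20 ms); and a contracting mid-ventricular short-axis heart
  with segment-specific T2\*, cyclic T2\* modulation over the cardiac cycle,
  a smooth background B0 field and a localized ~20 Hz/mm epicardial gradient;
* a **segmented k-space acquisition simulator** for five strategies —
  single-phase multi-echo (ME), interleaved multi-shot (MS), multi-breath-hold
  CINE (MB CINE), and the CINE references ME CINE / MS CINE — with echo
  interleaving, views-per-segment bookkeeping, prospective-trigger schedules
  and scan-duration accounting;
* **B0 field mapping** from dual-echo phase images, volume-selective
  linear + second-order **shimming**, and field statistics (peak-to-peak,
  histogram FWHM, gradients);
* bounded **mono-exponential T2\* fitting** (log-linear initialization, then
  trust-region nonlinear least squares);
* landmark-based **affine registration** of multi-breath-hold series;
* **six-sector segmental analysis** (segments 7–12 of the standard model)
  with ROI tracking across the cycle and paired diastole/systole statistics.

## The model

A spoiled gradient-echo voxel decays mono-exponentially with echo time,

```
S(TE) = S0 · exp(−TE / T2*),
```

and T2\* is estimated per voxel by fitting this decay over a
fat-water in-phase echo train (TE = 2.04 … 10.20 ms in 1.02 ms steps at
297.2 MHz / 3.3 ppm). Off-resonance Δf enters the complex signal phase as
`2π·Δf·TE`; a field map therefore follows from two echo phases as
`Δf = wrap(φ₂ − φ₁) / (2π·ΔTE)`. A macroscopic field gradient across a voxel
(total frequency spread *d*) attenuates the magnitude by the linear-phase
(sinc) intravoxel dephasing factor

```
|sin(π·d·TE) / (π·d·TE)|      (d in kHz, TE in ms),
```

which is what makes apparent T2\* depend on slice thickness. The acquisition
simulator renders the phantom in image space at the cardiac time of every
acquired k-space line and assembles per-echo k-spaces line by line, so motion
inconsistency between cardiac cycles — the artifact that distinguishes the
five strategies on a beating heart — is captured.

## Worked example

`examples/02_strategy_comparison.py` acquires the 20 ms cylinder with all
five strategies and fits T2\* voxelwise:

```
strategy  scan @240 lines   window   ROI T2* [ms]
ME                    25s    205ms    20.00 +- 0.26
MS                    49s    180ms    20.01 +- 0.35
MB_CINE             3x81s     36ms    20.00 +- 0.34
ME_CINE              121s     38ms    20.00 +- 0.26
MS_CINE              241s     36ms    20.01 +- 0.35
```

On a static object all five strategies agree with the 20 ms ground truth to
within hundredths of a millisecond — the segmented k-space ordering only
matters once the object moves. The scan-duration column is the segmented
bookkeeping (cardiac cycles = lines / views-per-segment, plus one
preparatory beat, at 60 bpm); the acquisition window is the k-space lines
acquired per cycle times TR.

`examples/04_cine_segmental_analysis.py` runs the full CINE chain on the
beating heart phantom (echoes interleaved over three misaligned
breath-holds, registration, fitting at 25 cardiac phases, segmental
statistics):

```
segment         ED [ms]  ES [ms]  cycle rise   truth
 7 anterior       15.98    13.73       26.1%   27.0%
 8 anteroseptal   20.17    17.24       26.8%   27.0%
 9 inferoseptal   16.97    14.68       27.4%   27.0%
10 inferior       11.95    10.44       26.1%   27.0%
11 inferolateral   9.50     8.31       27.0%   27.0%
12 anterolateral  12.65    10.93       27.5%   27.0%

paired t-test ED vs ES over segments: t = 7.67, p = 0.0006
```

Each segment's configured 27 % cyclic T2\* modulation (minimum in systole)
is recovered within about one percentage point at SNR ≈ 50, and the paired
end-diastole/end-systole comparison is strongly significant. The other
examples demonstrate B0 mapping and shimming (`03`, a ~430 Hz background
field collapsing to ~70 Hz under a second-order volume shim) and the
slice-thickness dependence of apparent T2\* under a through-plane gradient
(`05`).

A thin CLI mirrors the pipeline stages
(`cardiot2star simulate|b0map|shim|fit|register|segment|report`, each with
`--config/--seed/--out`); the library API above is the primary interface.

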