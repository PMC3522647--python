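# Methods

This note records the models, numerical choices and deliberate design
decisions behind `cardiot2star`, in the spirit of a simulation package's
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Signal model

Each voxel is described by ground-truth fields (S0, T2\*, off-resonance Δf,
fat fraction) on a 2D slice. The spoiled gradient-echo signal is

S(TE) = S0 · F_ss · exp(−TE/T2\*) · D(TE) · W(TE) · exp(i·2π·Δf·TE)

* **Mono-exponential decay** is the fitting model and the simulation truth;
  no multi-compartment behavior is generated.
* **Intravoxel dephasing** D(TE): a voxel spanning a total linear frequency
  spread *d* retains |sinc(d·TE)| of its magnitude (*d* in kHz, TE in ms) —
  the exact mean-phasor magnitude of a uniform frequency distribution, which
  the tests verify against a brute-force phasor sum to <1e−3. Through-plane
  dispersion is |df/dz| × slice thickness (the phantom carries an explicit
  per-voxel through-plane gradient field); in-plane dispersion is the
  finite-difference in-plane gradient component times the voxel size on each
  axis; the three sinc factors combine multiplicatively.
* **Fat-water modulation** W(TE): fat is a single resonance at the
  configured chemical shift (3.3 ppm at 297.2 MHz → 980.8 Hz, in-phase every
  1.02 ms). Default fat fraction is 0 everywhere; the heart phantom offers an
  optional epicardial fat rim.
* **Steady-state factor** F_ss = sin α(1−E1)/(1−cos α·E1) is available but
  **off by default**: the analysis chain fits the pure mono-exponential, and
  the protocols' low flip angle (20°) is chosen precisely to suppress
  T1-weighting differences. TR values for the mapping protocols are not
  published; defaults are inferred per protocol from the printed acquisition
  windows (ME 20.5 ms, ME CINE 19 ms, three-echo interleaved protocols
  12 ms) and satisfy TR > TE_max. With these, windows 205/38/36/36 ms follow
  exactly from views × excitations × TR; the single-phase MS window prints
  as 192 ms in the source protocol table but is 5 × 3 × 12 = 180 ms under
  any consistent TR — the discrepancy is in the source table, and scan
  durations (which the acceptance script checks) are unaffected.
* **Noise** is iid complex Gaussian added to both quadratures of the
  reconstructed images, making magnitudes Rician. No noise-floor or Rician
  bias correction is applied in fitting (none is used in the reference
  analysis chain); tests document the resulting small positive bias at low
  SNR instead of correcting it.

## Acquisition simulation

The simulator is image-space-rendered and k-space-assembled: for every
acquired line it evaluates the phantom at that line's cardiac time (nearest
phantom frame), Fourier transforms the rendered echo images, and copies
exactly that phase-encode row into the accumulating per-echo, per-phase,
per-breath-hold k-space. Gradient trajectories, relaxation during readout
and parallel imaging are not modeled; the artifacts of interest here —
motion inconsistency between cardiac cycles and intravoxel dephasing — are
captured at this level. Phase encoding is sequential (linear ordering);
every line is written exactly once (asserted internally).

Protocol bookkeeping ("views per segment" = k-space lines per cardiac cycle
per image; with E interleaved excitations the cycle spends views × E line
times): cardiac cycles = ceil(lines / views) + one preparatory cycle, and
scan seconds = cycles × 60/heart-rate. One preparatory beat reproduces the
published phantom-study durations exactly (25/49/3×81/121/241 s at 240
lines, 60 bpm). Echo interleaving assigns excitation *i* the echoes
*i*, *i*+E, *i*+2E, …; MB CINE gives each excitation's echo subset its own
breath-hold. Prospective CINE triggering leaves a 100 ms end-diastolic gap;
the n phases are spaced over (cycle − gap)/n.

Simulated acquisitions are fully sampled; the accelerated in vivo variants
(GRAPPA R = 2/3) are out of scope, so in vivo breath-hold times are not
reproduced, only the phantom-protocol timing.

## Phantoms

* **Cylinders.** The long-T2\* phantom is a 150 mm cylinder (base T2\*
  30 ms) with a 5 mm water tube and a 0.5 mm air capillary. The capillary is
  sub-voxel at the default resolution and is voxelized as (at least) the
  nearest voxel with S0 = 0; its field is a 2D dipole A·cos 2θ/r²
  (transverse susceptibility cylinder), amplitude default 80 Hz·mm² — a free
  parameter (the true susceptibility difference is unstated) calibrated once
  so T2\* shortening is visible near the inclusion at 8 mm slices. The
  medium-T2\* phantom is an 80 mm cylinder at exactly 20 ms. Both accept an
  optional uniform through-plane gradient for slice-thickness sweeps.
* **Heart.** A mid-ventricular annulus (end-diastolic radii 22/30 mm) with
  blood pool and surrounding tissue on a 128×128 grid at the in vivo
  1.125 mm resolution, 25 phases per cycle at 60 bpm. Contraction is an
  analytic radial interpolation between end-diastole and end-systole via C1
  cosine half-waves peaking at the end-systolic fraction (0.36 of the
  cycle); the end-systolic epicardial radius defaults to the
  area-conserving (incompressible-wall) value, so systolic wall thickness
  (10.7 mm) exceeds diastolic (8 mm) and myocardial area is conserved to
  discretization (<1 % in tests). Each 60° sector carries its segment's
  T2\*; the cycle modulation multiplies the end-systolic (minimum) values by
  1 + a·w(u) with a smooth periodic w that is 0 at end-systole and 1 at 0.76
  of the cycle (after the onset of diastole). The default uniform amplitude
  a = 0.27 realizes a 27 % max/min swing in every segment; alternatively
  (amplitude = None) each segment's amplitude comes from its stored
  end-diastolic/end-systolic value pair. The stored default segment values
  are the published end-diastolic and end-systolic mid-ventricular rows.
  The off-resonance field is a background polynomial within the 2D shim span
  (linear + x²−y² + xy, several hundred Hz peak-to-peak across the heart)
  plus a localized epicardial gradient: a Gaussian-enveloped ramp (σ = 3 mm,
  centered 1 mm outside the end-diastolic epicardium at 150° display angle —
  the inferior/inferolateral border) with 20 Hz/mm in-plane and 20 Hz/mm
  through-plane magnitude (80 Hz/voxel at 4 mm slices). The field is static
  over the cycle, matching the observation that cardiac field maps vary
  negligibly with phase. Breath-hold misalignment applies a recorded random
  shift + shear to each hold's parameter maps (bilinear resampling; masks by
  nearest neighbor).

What the generator does *not* emulate: real myocardial trabecular structure
and fiber architecture, blood flow and inflow enhancement, B1+
inhomogeneity (the real protocol's ~40 % signal shading), trigger jitter and
arrhythmia, respiratory drift within a hold, and the microscopic
susceptibility that physically causes T2\* contrast (T2\* is prescribed, not
emergent). Passing tests therefore demonstrate the correctness of the
processing chain under known ground truth, not in vivo accuracy.

## Field mapping and shimming

Δf = wrap(φ₂−φ₁)/(2π·ΔTE) with the wrap to [−π, π); with ΔTE = 1.02 ms the
unambiguous range is ±490 Hz, which covers post-shim fields of interest. No
spatial unwrapping is performed; aliasing beyond Nyquist is documented, not
corrected. Shimming is least-squares subtraction of the basis surface
{x, y, z, z², zx, zy, x²−y², xy} over the ROI (coordinates in mm relative
to the ROI centroid; a constant frequency-offset term is included, which
affects neither peak-to-peak nor demeaned RMS); for 2D phantoms the
z-dependent terms drop, leaving {1, x, y, x²−y², xy}. The projection
property guarantees the ROI RMS never increases. Histogram FWHM uses 10 Hz
bins with linear interpolation at the half-maximum crossings.

## T2\* fitting

Stage 1: OLS line through (TE, ln S) over the strictly positive samples;
T2\* = −1/slope, clipped to (0.1, 200] ms (bounds bracketing all plausible
myocardial/phantom values with margin); S0 is initialized from the sample at
the minimum TE — the estimator quoted for the reference chain; it
underestimates S0 by exp(−TE_min/T2\*), which stage 2 absorbs, so the
ambiguity between this rule and the log-linear intercept only affects the
starting point. Stage 2: bounded nonlinear least squares of
S0·exp(−TE/T2\*) on the magnitude samples (all of them, including
non-positive ones), trust-region-reflective with analytic Jacobian; a
non-improving or failed solve retains the initialization with a status
flag. Voxels are independent; no spatial regularization.

For whole-map fitting a vectorized bounded Levenberg–Marquardt (identical
model, bounds and objective, batched over voxels) replaces the per-voxel
scipy call for speed; a test pins the two paths together to 5×10⁻³ ms on a
noisy fixture. Noiseless recovery is exact to <1e−6 relative error; with
intravoxel dispersion the apparent T2\* is biased low by construction (the
sinc factor steepens the decay), which is the mechanism behind the
slice-thickness trend.

## Registration

"Shift and shear" alignment is implemented as the full 2D affine class with
least-squares landmark estimation (exact for three non-collinear pairs);
translation-only and shear-only restrictions are available since the exact
parameterization in the reference chain is unstated. One transform per
breath-hold is estimated (not per cardiac phase) and applied to the
magnitude images by bilinear resampling before fitting. In tests and the
pipeline, landmarks derive from the generator's recorded ground-truth
transforms, standing in for manually placed points; the CLI accepts a
landmark CSV (hold, x_src, y_src, x_dst, y_dst).

## Segmental analysis

Display angles are measured clockwise from anterior (image top; the image
row axis runs anterior → inferior for short-axis views). The anterior RV
insertion (default 330°) is the segment 7/8 boundary; counting
counterclockwise from it yields segments 8…12, 7, placing 7 anterior and 10
inferior. Sectors are re-derived at every cardiac phase from that phase's
myocardial mask and centroid, eroded by one voxel so only compact myocardium
enters; blood-pool voxels are never labeled. Segment means require at least
10 valid-fit voxels, otherwise the row is flagged (never dropped).
End-diastole/end-systole are identified from the phantom truth as the
phases of maximal/minimal cavity area — a stand-in criterion, since the
operator-defined phase matching of the reference analysis is not
reproducible. The paired diastole/systole comparison is the closed-form
two-sided paired t-test (mean difference over sd/√n, n−1 df), with the
p-value from the t CDF; no multiple-testing correction is applied,
mirroring the reference analysis. Percent increase is 100·(max−min)/min of
the per-segment phase curve.

## Problem sizes and determinism

Default study conditions: heart phantom 128×128 at 1.125 mm, 25 phases,
60 bpm; cylinder phantoms on the 320×240 phantom-protocol grid or scaled
grids of the same resolution for compact experiments; SNR ≈ 50 at the first
echo for the end-to-end CINE study (σ derived from the first-echo
myocardial magnitude), SNR ≈ 100 for strategy-equivalence checks. Every
random draw (noise, breath-hold motion) flows from a single integer seed
through one `numpy` generator, and the pipeline's report files are
byte-identical across reruns of the same config + seed (tested). Geometry
metadata (matrix, FOV, slice thickness, orientation) travels unchanged
through every stage; the in vivo default geometry keeps the exact
FOV/matrix quotient (1.125 mm) rather than the rounded 1.1 mm print.

## Known limitations

Single 2D slice (no multi-slice/3D); fully sampled k-space only; no B1+ or
coil modeling; no deformable motion (affine breath-hold misalignment only);
no fat-water separation or multi-compartment fitting; dipole and epicardial
field amplitudes are calibrated free parameters, not susceptibility-derived
values.
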