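# Methods

## Optical model

The forward model is scalar Fresnel diffraction through the Fourier
light-field train. An emitter at axial position `z` (µm) produces, at the
relayed pupil plane, the aperture-limited defocus field

    P_z(ν) = 1{|ν| ≤ NA/λ} · exp(i 2π z √((n/λ)² − ν²)) · exp(i φ_ab(ν)),

with `ν` the sample-space spatial frequency (cyc/µm), `n` the immersion
index and `φ_ab` an optional aberration phase. The pupil coordinate at
the microlens array (MLA) plane is `u = ν λ f_FL / M_obj`, giving a
relayed pupil radius `NA · f_FL / M_obj` = 3.99 mm for the default
100×/1.45 train with the 275 mm Fourier lens. The MLA transmittance is a
sum of circular lenslet apertures (diameter = pitch) carrying thin-lens
quadratic phases `exp(−iπ|u−c_j|²/(λ f_ML))`; one Fresnel propagation
over `f_ML` (a single FFT once the quadratic phases are combined — they
cancel pointwise into per-lenslet tilts, so the product is well sampled
even though each factor alone is not) lands the field on the camera.
Squared modulus per axial plane gives the PSF stack.

Key consequences built into the model:

- Each elemental image of a sample point sits exactly at its lenslet
  center; lateral sample shifts move it by `M_eff = M_obj f_ML / f_FL`
  (42.5× by default), so the sample-scale pixel is
  `pixel_cam / M_eff` (0.153 µm at the native 6.5 µm camera pitch).
- Defocus displaces the three spots by parallax — the depth-encoding
  mechanism. The ±z planes are therefore *not* globally mirror images;
  they match after point reflection about each spot's own center (the
  test suite verifies correlation ≥ 0.99 in that form).
- Per-plane energy is exactly conserved (Parseval) until defocused spots
  reach the sensor crop.

**Assumptions.** Scalar (not vectorial) diffraction despite NA 1.45 — an
accepted model error, since the instrument's own resolution regime
(400–600 nm) sits well above the vectorial limit; no polarization, no
spectral crosstalk, shift-invariant PSF across the field.

## MLA geometry

The custom array's pitch is not published; the default (3.3 mm) is
chosen so that (a) exactly three hexagonally packed lenslets fit wholly
inside the relayed pupil when the optical axis sits at a lattice hole —
the three-view design — and (b) the elemental field of view
`pitch / M_eff` is 77.6 µm, matching the 70–80 µm hydrodynamically
focused core. These two constraints cannot be met under the naive
"lenslet centers inside the pupil" counting rule, so elemental
membership is defined as *aperture fully inside the pupil, or pupil
fully inside the aperture* (an unvignetted beam); partially illuminated
neighbours are treated as masked, as a custom array would block stray
sub-images. `mla_alignment="lenslet"` centers a lenslet on the axis
instead, whose infinite-pitch limit is plain Fourier imaging — used as a
single-aperture control (its in-focus width matches the Airy value for
the sub-aperture NA = (pitch/2)·M_obj/f_FL ≈ 0.6).

The "hybrid" PSF is realized as the ideal model times an optional
calibration `AberrationMap` (named low-order Zernike modes in waves RMS,
and/or a measured pupil phase map); an all-zero map reproduces the ideal
stack bit-for-bit.

## Numerical grids

The PSF is computed on the camera pixel grid itself (FFT center-pixel
convention at `N//2`), so PSF planes and frames share one grid exactly.
The pupil band limit requires an effective pitch below
`λ f_ML / (2 · pupil radius)` (9.98 µm at 680 nm); when the configured
camera pitch is coarser, `build_psf_stack` automatically computes the
field on an integer-oversampled grid and box-bins — i.e. integrates over
pixel footprints. At the native 6.5 µm pitch no oversampling is needed.

**Desk scale.** `OpticalConfig.reduced()` (512 px at 9 µm, ±2 µm axial
span by default) keeps every optical parameter of the instrument and
only coarsens the sensor; the full 1024×1024×101 grid is available for
parity runs. One geometric consequence: the elemental-spot triangle
spans ±44.8 µm at sample scale, so the 512-px field keeps all three
views only for objects within roughly ±10 µm of the axis (the full
sensor has the same property outside the flow core). The desk-scale
population studies therefore narrow the core (`core_width = 12 µm`) so
every object is imaged with complete view sets, mirroring the matched
core/field design of the instrument.

## Phantoms, flow and noise

Objects are spheres, spherical shells, puncta sets and micronuclei sets
with uniform fluorophore density (photons/µm³ per strobe). Bead
brightness therefore scales with volume, as for uniformly dyed
microspheres. Rasterization is partial-volume: boundary voxels get the
linear-ramp occupancy of the surface cutting the voxel (≤ 1% volume
error at 20 voxels/diameter); sub-voxel features are trilinearly
splatted so their integral is conserved exactly.

Flow is kinematic: objects advance along +x at `flow_speed` (default
4.5 mm/s) and each strobe samples positions at its timestamp; rendering
is quasi-static per strobe except for a line-kernel motion blur of
length `v·τ` (0.45 µm at the 100 µs default — below the lateral
resolution, which is the point of stroboscopic illumination). Two-color
sequences alternate channels frame by frame; the two strobes of a cycle
are `t2` apart (default 200 µs), so paired frames see nearly identical
positions. Lateral positions are uniform across the core, axial uniform
over a configurable span truncated to the PSF range (the instrument's
positional distribution is not published).

Camera counts are `gain·Poisson(photons) + N(0, σ_read) + offset`
(defaults 2 counts/photon, 3.2 counts, 100 counts — order-of-magnitude
sCMOS values; the real calibration is not published). Cell phantom
densities default to 5×10³ photons/µm³, putting peak SNR in the 5–15
range where the denoising stage matters; microspheres default to
4×10⁵ photons/µm³, reflecting that the physical beads are bright
(near but below 16-bit saturation for the 4 µm class). With the noise
model set to `None` rendering is exactly deterministic; with a seed it
is bit-reproducible.

What the generator does **not** emulate: cell deformation in flow,
hydrodynamics (the core is a static width), photobleaching, spectral
bleed-through, sCMOS fixed-pattern noise, debris and clumping, and
shift-variant aberrations. Passing tests therefore demonstrate the
correctness and resolution of the computational chain under the stated
optical model, not robustness to those instrument realities.

## Reconstruction pipeline

Stages run in acquisition order. Screening keeps frames whose
background-subtracted pixels exceed a robust z-score (default 6) with at
least 4 such pixels, and drops frames whose largest foreground blob
exceeds `max_object_extent` (debris rule). Two-color pairing joins
cycle-aligned adjacent opposite-channel frames only — an odd frame and
the next even frame are a full frame period apart and would misregister
the channels. Background subtraction is grayscale opening with a
`(2r+1)`-pixel separable structuring element (the fast variant of the
rolling-ball estimate; default r = 50 px, far above any object radius).
The denoising stand-in is an Anscombe transform (gain/offset-aware when
the noise model is known) followed by BayesShrink wavelet shrinkage and
the inverse transform; it is behind a plug-in interface because the
instrument's own denoiser is prior published work — the pipeline
contract is only SNR gain without centroid bias, which the tests
enforce. After denoising the residual median is subtracted: clipping
negatives leaves a small positive pedestal in empty background which
Richardson-Lucy would otherwise redistribute into ghost structure.

Richardson-Lucy uses the multiplicative update `x ← x·Aᵀ(y/Ax)/Aᵀ1`
with `A` the same per-plane convolve-and-sum operator the renderer uses,
uniform positive initialization, division guard `ε = 10⁻¹²·max(y)`, and
no regularization (plain RL). Boundary handling pads frames to
linear-convolution size and crops back, so sensor-edge clipping is part
of the operator and its adjoint. The operator runs in float32 by
default (float64 available; the small-instance tests verify agreement
with a dense-matrix implementation of the same update to 1e-6 in
float64). The three elemental images are deconvolved jointly — the PSF
kernel contains all three spots — so "elemental image selection"
reduces to cropping the sensor region containing them. Iteration
defaults follow instrument practice: 30 for beads, 50–80 for cells.

## Cytometry

Segmentation defaults to Otsu + 3D 26-connectivity with a minimum-size
filter; `fraction_of_max` (20%) suits single bright objects, and
`peak_fraction` — per-peak watershed with each basin cut at 20% of its
own peak, optionally on a Gaussian-smoothed volume (σ in voxels) —
handles fields whose objects span the ~8000× brightness range of a
0.2–4 µm bead mixture. Smoothing suppresses the speckle that iterative
deconvolution leaves inside bright objects; intensities are always
summed from the raw volume. Ellipsoid radii come from intensity-weighted
second moments (`R_i = √(5 λ_i)`, the uniform-ellipsoid identity), with
a voxel-variance correction (`voxel²/12`) so single-voxel extents are
not reported as zero. Micronuclei dispersion is the mean distance of
component centroids to their intensity-weighted common centroid — zero
for an intact nucleus by definition. Enclosure uses the convex hull of
the micronuclei voxel set (Delaunay membership); the instrument's
geometric definition is not published, and the hull is the least
arbitrary operationalization. Population counting fits full-covariance
Gaussian mixtures on log-volume/log-intensity for 1–6 components and
keeps the BIC optimum. Size histograms use Freedman–Diaconis bins with
least-squares Gaussian fits on bin centers (sample-moment fallback).
Reporter gating defaults to an Otsu split of log-intensity, override by
an explicit threshold; the apoptosis criterion is micronuclei count > 1,
both exposed as configuration because the instrument's exact rules are
unpublished.

## Problem sizes used in the checks

The test suite and the acceptance script run the desk-scale grid
(512 px at 9 µm; 31–41 axial planes; 30 RL iterations; 40-bead mixture
in ~11 dilute frames; depth-of-focus sweep at 17 axial positions with
0.25 µm plane spacing). These sizes reproduce the bounded claims — the
42.5× identity, 101-plane/3-view geometry, ≤600 nm reconstructed 3D
FWHM, ≥6 µm depth of focus, four-population recovery, and the 0.55 N:C
worked example — at desk scale; the noiseless simulated resolution
(≈215/215/288 nm) is naturally finer than the hardware-measured values,
which include residual calibration error and noise.

## Known limitations

- Scalar diffraction and a shift-invariant PSF; no field-dependent
  aberrations or per-lens registration errors (offsets are config
  fields, defaulting to the ideal geometry).
- The published MLA pitch, fill factor and hybrid-PSF calibration are in
  unpublished supplements; the defaults here are derived from the
  printed constraints and are config-overridable.
- The denoising stage is a stand-in honoring the pipeline contract, not
  a reimplementation of the instrument's algorithm.
- Sub-resolution objects (the 200 nm bead class) segment at the point
  response of the system, so their apparent diameter reflects
  resolution, not size — as in the hardware, where measured bead
  profiles are the convolution of bead and PSF.
- GPU parity (0.2 s/iteration on the full grid) is out of scope; the
  implementation is single-threaded FFT on CPU.
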