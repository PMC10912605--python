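# lfcyto

A digital twin of a **light-field flow cytometer (LFC)**: an imaging flow
cytometer that records the full 3D structure of every cell crossing the
field in a *single* camera frame, by imaging through a microlens array
placed at a relayed pupil plane of a high-NA epi-fluorescence microscope.

The package is for computational microscopists and cytometrists who want
to study, extend or validate the LFC processing chain without the
instrument: it simulates the optics end to end, generates realistic
synthetic samples in flow, reconstructs volumes the same way the
instrument's software does, and extracts the 3D single-cell statistics
that the modality is used for.

## What it implements

**Optics (`lfcyto.optics`).** A scalar wave-optics model of the Fourier
light-field train: objective (100×/1.45 NA oil), tube lens, Fourier lens
(f = 275 mm), and a custom hexagonal microlens array (f = 117 mm) at the
relayed pupil, camera one lenslet focal length behind. Exactly three
lenslets sit inside the pupil, so a point emitter maps to three
diffraction-limited spots whose parallax encodes depth. Each elemental
image has effective magnification

&nbsp;&nbsp;&nbsp;&nbsp;M_eff = M_obj · f_ML / f_FL = 100 · 117 / 275 = **42.5×**,

trading magnification for a 70–80 µm field per view. The defocused pupil
field is `exp(i 2π z √((n/λ)² − ν²))` on the aperture `|ν| ≤ NA/λ`; one
Fresnel transform through the MLA yields each PSF plane. An optional
Zernike/measured-phase calibration term turns the ideal PSF into the
instrument's *hybrid* PSF.

**Phantoms in flow (`lfcyto.phantom`).** Microsphere mixtures and
simplified cells (membrane shells, nuclei, micronuclei sets, organelle
puncta, reporter expression) with analytic ground truth, placed in a
hydrodynamically focused core, advanced along the flow axis between
strobes, rasterized with partial-volume accuracy, blurred by the
per-plane light-field convolution, and corrupted with an sCMOS noise
model (Poisson shot noise + Gaussian read noise + offset). Sequences
alternate color channels frame by frame for two-color acquisition.

**Reconstruction (`lfcyto.reconstruct`).** The instrument's pipeline:
blank/debris screening → two-color pairing → rolling-ball background
subtraction → variance-stabilised wavelet denoising (a stand-in with a
plug-in interface) → padding to the PSF grid → **3D Richardson-Lucy
deconvolution** `x ← x · Aᵀ(y/Ax) / Aᵀ1`, where `A` is the same
convolve-and-sum operator used to render the frames. 30 iterations for
beads, 50–80 for cells.

**Cytometry (`lfcyto.cytometry`).** Segmentation (Otsu /
fraction-of-max / per-peak watershed), per-object volume, equivalent
diameter `(6V/π)^{1/3}`, FWHM, moment-fitted ellipsoid radii
(Ra ≥ Rb ≥ Rc), N:C volume ratios, micronuclei count/volume/dispersion,
mitochondria-in-micronuclei enclosure, BIC-selected Gaussian-mixture
population counting, Gaussian-fitted size distributions, and
Otsu-gated reporter-positive fractions.

**I/O and CLI (`lfcyto.io`, `lfcyto.cli`).** Multipage TIFF frames
(1024×1024 and 1024×900 dialects), float TIFF PSF/volume stacks with
voxel metadata, flat YAML configs, CSV feature tables, JSON provenance,
and an `lfc` command with `build-psf`, `simulate`, `reconstruct`,
`analyze` and `report` subcommands.

## Worked example

```python
import numpy as np
import lfcyto as lf

cfg = lf.OpticalConfig.reduced()            # 512 px @ 9 µm, ±2 µm axial
print(f"effective magnification: {lf.effective_magnification(cfg):.3f}x")
print(f"elemental field of view: {cfg.elemental_fov:.1f} um")
psf = lf.build_psf_stack(cfg, channel=2)    # 680 nm far-red channel
print(f"PSF stack: {psf.n_planes} planes, voxel {psf.voxel_xy:.3f} x {psf.z_step:.1f} um")

bead = lf.PhantomObject("bead", (0, 0, 0),
                        [lf.Component("core", lf.Sphere(0.2), 0, 4e5)])
dens = lf.voxelize(bead, psf.voxel, (psf.n_planes, 512, 512))[0]
frame = lf.render_lightfield_frame(dens, psf)
vol = lf.richardson_lucy_3d(frame, psf, iterations=30)
zi, yi, xi = np.unravel_index(np.argmax(vol.data), vol.data.shape)
for ax in "xyz":
    print(f"reconstructed 200-nm bead FWHM {ax}: "
          f"{lf.measure_fwhm(vol, (zi, yi, xi), ax):.0f} nm")

cell = lf.make_cell_phantom("membrane_nucleus", d_cell=7.99, d_nuc=6.57)
print(f"ground-truth N:C ratio: {cell.truth['nc_ratio']:.3f}")
```

prints (about half a minute on one CPU):

```
effective magnification: 42.545x
elemental field of view: 77.6 um
PSF stack: 41 planes, voxel 0.212 x 0.1 um
reconstructed 200-nm bead FWHM x: 215 nm
reconstructed 200-nm bead FWHM y: 215 nm
reconstructed 200-nm bead FWHM z: 288 nm
ground-truth N:C ratio: 0.556
```

The sub-diffraction bead reconstructs to ~200–300 nm in all three
dimensions — deconvolution of the three-view light-field data restores
near-diffraction-limited 3D resolution even though each sub-aperture
only has NA ≈ 0.6. The N:C ratio is the volumetric
nuclear-to-cytoplasmic ratio of a two-color T-cell phantom at the
cohort-mean diameters.

The same chain is available from the shell:

```sh
lfc build-psf --out psf.tif
lfc simulate --psf psf.tif --kind beads --seed 1 --out frames.tif
lfc reconstruct --psf psf.tif --frames frames.tif --iters 30 --out vols/
lfc analyze --volumes vols/ --out features.csv
lfc report --features features.csv --out report/
```

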