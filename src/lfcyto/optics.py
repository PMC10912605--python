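"""Wave-optics forward model of the Fourier light-field train.

The instrument places a microlens array (MLA) at the relayed pupil plane of
a high-NA epi-fluorescence microscope: the native image formed by the
objective (magnification ``m_obj``, numerical aperture ``na``) and tube lens
(``f_tube``) is Fourier-transformed by a Fourier lens (``f_fl``) so that the
objective pupil is re-imaged onto the MLA.  Each lenslet (focal length
``f_ml``, pitch ``mla_pitch``) then forms a perspective *elemental image* of
the sample on the camera, one lenslet focal length behind the array.  With
the default geometry exactly three lenslets sit fully inside the pupil disc,
so every point emitter maps to three diffraction-limited spots whose
parallax encodes depth.

Scalar Fresnel diffraction is used throughout.  The pupil field of an
emitter defocused by ``z`` is the aperture-limited defocus phase
``exp(i 2π z sqrt((n/λ)² − ν²))`` on the sample-space frequency grid ``ν``;
multiplying by the MLA transmittance and propagating one lenslet focal
length (a single Fresnel transform) yields the sensor field.  Squared
modulus, stacked over a uniform grid of axial planes, gives the system PSF
used both to render synthetic frames and as the deconvolution kernel.

Units: focal lengths, pitch and pupil-plane coordinates in mm; wavelengths
in nm; camera pitch and sample-space coordinates in µm; axial positions in
µm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.fft as _fft

from .errors import (
    ConfigurationError,
    DomainError,
    GeometryWarning,
    SamplingError,
)

__all__ = [
    "OpticalConfig",
    "PupilField",
    "PSFStack",
    "AberrationMap",
    "effective_magnification",
    "pupil_field",
    "mla_transmittance",
    "lenslet_centers",
    "elemental_centers",
    "build_psf_stack",
    "min_oversample",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalConfig:
    """Validated record of every optical parameter of the instrument.

    Defaults reproduce the reference system: a 100×/1.45 NA oil objective
    (immersion index 1.515), a 275 mm Fourier lens, a custom hexagonal MLA
    with 117 mm lenslets, and a 6.5 µm sCMOS camera.  The tube lens is the
    manufacturer-standard 200 mm.  ``mla_pitch`` is chosen so that exactly
    three lenslets fit inside the relayed pupil and the elemental field of
    view at the sample is 70–80 µm; it is a plain field so a measured value
    can override it.
    """

    na: float = 1.45
    m_obj: float = 100.0
    f_tube: float = 200.0        # mm
    f_fl: float = 275.0          # mm, Fourier lens
    f_ml: float = 117.0          # mm, microlens
    mla_pitch: float = 3.3       # mm, lenslet center-to-center
    mla_rotation: float = 0.0    # rad
    mla_alignment: str = "hole"  # pupil centered at a lattice "hole" or "lenslet"
    n_imm: float = 1.515
    wavelengths: tuple = (515.0, 580.0, 680.0)   # nm, emission per channel
    pixel_cam: float = 6.5       # µm
    sensor_shape: tuple = (1024, 1024)           # (rows, cols) px
    z_range: float = 5.0         # µm, axial half-extent
    z_step: float = 0.1          # µm

    def __post_init__(self):
        if not (0.0 < self.na < self.n_imm):
            raise ConfigurationError(
                f"need 0 < NA ({self.na}) < immersion index ({self.n_imm})")
        for name in ("m_obj", "f_tube", "f_fl", "f_ml", "mla_pitch",
                     "pixel_cam", "z_range", "z_step"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if len(self.sensor_shape) != 2 or min(self.sensor_shape) < 16:
            raise ConfigurationError(f"bad sensor_shape {self.sensor_shape}")
        if not self.wavelengths:
            raise ConfigurationError("need at least one emission wavelength")
        if self.mla_alignment not in ("hole", "lenslet"):
            raise ConfigurationError(
                f"mla_alignment must be 'hole' or 'lenslet', got {self.mla_alignment!r}")
        object.__setattr__(self, "wavelengths", tuple(float(w) for w in self.wavelengths))
        object.__setattr__(self, "sensor_shape", tuple(int(s) for s in self.sensor_shape))

    # ---- derived quantities ----

    @property
    def m_eff(self) -> float:
        """Effective magnification of one elemental image."""
        return effective_magnification(self)

    @property
    def pupil_radius(self) -> float:
        """Radius of the relayed pupil disc at the MLA plane (mm)."""
        return self.na * self.f_fl / self.m_obj

    @property
    def n_planes(self) -> int:
        """Number of axial PSF planes; odd, with a plane at z = 0."""
        n = int(round(2.0 * self.z_range / self.z_step)) + 1
        if n % 2 == 0:
            n += 1
        return n

    @property
    def z_planes(self) -> np.ndarray:
        """Axial plane positions (µm), symmetric about 0."""
        n = self.n_planes
        return (np.arange(n) - n // 2) * self.z_step

    @property
    def grid_size(self) -> int:
        """Side of the square computation grid (px); covers the sensor."""
        return max(self.sensor_shape)

    @property
    def voxel_xy(self) -> float:
        """Lateral sample-scale pixel size, ``pixel_cam / m_eff`` (µm)."""
        return self.pixel_cam / self.m_eff

    @property
    def elemental_fov(self) -> float:
        """Elemental field of view at the sample, ``pitch / m_eff`` (µm)."""
        return self.mla_pitch * 1e3 / self.m_eff

    def wavelength(self, channel: int) -> float:
        try:
            return self.wavelengths[channel]
        except IndexError:
            raise DomainError(f"channel {channel} has no configured wavelength")

    @classmethod
    def reduced(cls, sensor: int = 512, pixel_cam: float = 9.0,
                z_range: float = 2.0, z_step: float = 0.1, **kw) -> "OpticalConfig":
        """Desk-scale configuration for tests and examples.

        Coarsens the camera pitch to 9 µm (still above the field band limit
        of the 1.45-NA pupil, which requires < 9.98 µm at 680 nm) and crops
        the sensor, leaving all optics untouched.
        """
        return cls(sensor_shape=(sensor, sensor), pixel_cam=pixel_cam,
                   z_range=z_range, z_step=z_step, **kw)

    def with_(self, **kw) -> "OpticalConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


def effective_magnification(config: OpticalConfig) -> float:
    """Magnification of one elemental image, ``m_obj · f_ml / f_fl``.

    The MLA sub-aperture re-images the sample at a lower magnification than
    the objective alone (42.5× for the default 100×/117 mm/275 mm train),
    which is what buys the enlarged field of view per elemental image.
    """
    if not isinstance(config, OpticalConfig):
        raise ConfigurationError("expected an OpticalConfig")
    return config.m_obj * config.f_ml / config.f_fl


# --------------------------------------------------------------------------
# pupil-plane grids
# --------------------------------------------------------------------------

def _pupil_grid(config: OpticalConfig, wavelength_nm: float, n: int | None = None,
                oversample: int = 1):
    """Pupil-plane coordinate grids matched to the sensor FFT grid.

    Returns ``(ux, uy, du)`` where ``ux, uy`` are physical MLA-plane
    coordinates in mm on an ``n × n`` grid whose FFT lands exactly on the
    camera pixel grid: ``du = λ f_ml / (n · dx)``.
    """
    if n is None:
        n = config.grid_size * oversample
    lam_mm = wavelength_nm * 1e-6
    dx_mm = config.pixel_cam * 1e-3 / oversample
    du = lam_mm * config.f_ml / (n * dx_mm)
    if n * du < 2.0 * config.pupil_radius:
        raise SamplingError(
            f"camera pitch {config.pixel_cam / oversample:.2f} µm cannot hold the "
            f"pupil band limit (needs < {wavelength_nm * 1e-3 * config.f_ml / (2 * config.pupil_radius):.2f} µm); "
            "reduce pixel_cam or increase oversample")
    u = (np.arange(n) - n // 2) * du
    ux, uy = np.meshgrid(u, u)
    return ux, uy, du


def _freq_scale(config: OpticalConfig, wavelength_nm: float) -> float:
    """Sample-space spatial frequency (cyc/µm) per mm of pupil coordinate."""
    lam_mm = wavelength_nm * 1e-6
    return config.m_obj / (lam_mm * config.f_fl) * 1e-3


# --------------------------------------------------------------------------
# aberrations
# --------------------------------------------------------------------------

def _zernike(term: str, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    # RMS-normalised Zernike polynomials on the unit pupil
    r2 = rho * rho
    table = {
        "defocus":   np.sqrt(3.0) * (2 * r2 - 1),
        "astig_0":   np.sqrt(6.0) * r2 * np.cos(2 * theta),
        "astig_45":  np.sqrt(6.0) * r2 * np.sin(2 * theta),
        "coma_x":    np.sqrt(8.0) * (3 * r2 - 2) * rho * np.cos(theta),
        "coma_y":    np.sqrt(8.0) * (3 * r2 - 2) * rho * np.sin(theta),
        "trefoil_x": np.sqrt(8.0) * rho ** 3 * np.cos(3 * theta),
        "trefoil_y": np.sqrt(8.0) * rho ** 3 * np.sin(3 * theta),
        "spherical": np.sqrt(5.0) * (6 * r2 * r2 - 6 * r2 + 1),
    }
    try:
        return table[term]
    except KeyError:
        raise DomainError(f"unknown Zernike term {term!r}; "
                          f"choose from {sorted(table)}")


@dataclass
class AberrationMap:
    """Calibration term turning the ideal PSF into the hybrid PSF.

    ``zernike`` maps named low-order modes to coefficients in waves RMS,
    per channel index (a plain dict applies to every channel).  An optional
    measured ``phase_map`` (radians, on the pupil grid) is added on top.
    An all-zero map reproduces the ideal model exactly.
    """

    zernike: dict = field(default_factory=dict)
    phase_map: np.ndarray | None = None

    def coefficients(self, channel: int) -> dict:
        if self.zernike and all(isinstance(v, dict) for v in self.zernike.values()):
            return self.zernike.get(channel, {})
        return self.zernike

    def phase(self, rho: np.ndarray, theta: np.ndarray, channel: int = 0) -> np.ndarray:
        """Aberration phase in radians on the normalised pupil."""
        ph = np.zeros_like(rho)
        for term, coeff in self.coefficients(channel).items():
            if coeff:
                ph += 2.0 * np.pi * float(coeff) * _zernike(term, rho, theta)
        if self.phase_map is not None:
            if self.phase_map.shape != rho.shape:
                raise DomainError("measured phase map does not match the pupil grid")
            ph = ph + self.phase_map
        return ph

    def is_null(self, channel: int = 0) -> bool:
        return (self.phase_map is None
                and not any(self.coefficients(channel).values()))


# --------------------------------------------------------------------------
# pupil field
# --------------------------------------------------------------------------

@dataclass
class PupilField:
    """Complex field at the relayed pupil for one emitter depth.

    ``amplitude`` is sampled on the square FFT grid; ``freq_step`` is the
    sample-space frequency spacing in cyc/µm.  The support is the disc
    ``|ν| ≤ na/λ``; at z = 0 with no aberration the phase inside the
    support is constant.
    """

    amplitude: np.ndarray
    freq_step: float       # cyc/µm
    wavelength: float      # nm
    z: float               # µm

    @property
    def energy(self) -> float:
        return float(np.sum(np.abs(self.amplitude) ** 2))


def pupil_field(config: OpticalConfig, z: float, channel: int = 0,
                aberration: AberrationMap | None = None,
                oversample: int = 1) -> PupilField:
    """Aperture-limited defocus field at the relayed pupil plane.

    amplitude = mask(ν ≤ na/λ) · exp(i 2π z √((n_imm/λ)² − ν²)) · exp(i φ_ab)

    with ``ν`` the sample-space radial frequency.  ``z`` must satisfy
    ``|z| ≤ z_range``.
    """
    if abs(z) > config.z_range + 1e-9:
        raise DomainError(f"|z| = {abs(z)} µm exceeds z_range = {config.z_range} µm")
    lam_nm = config.wavelength(channel)
    lam_um = lam_nm * 1e-3
    ux, uy, du = _pupil_grid(config, lam_nm, oversample=oversample)
    s = _freq_scale(config, lam_nm)
    nu2 = (ux * ux + uy * uy) * s * s
    nu_max = config.na / lam_um
    mask = nu2 <= nu_max * nu_max
    kz = 2.0 * np.pi * np.sqrt(np.maximum((config.n_imm / lam_um) ** 2 - nu2, 0.0))
    amp = mask * np.exp(1j * kz * z)
    if aberration is not None and not aberration.is_null(channel):
        rho = np.sqrt(nu2) / nu_max
        theta = np.arctan2(uy, ux)
        amp = amp * np.exp(1j * aberration.phase(rho, theta, channel))
        amp *= mask
    return PupilField(amplitude=amp, freq_step=du * s, wavelength=lam_nm, z=z)


# --------------------------------------------------------------------------
# microlens array
# --------------------------------------------------------------------------

def lenslet_centers(config: OpticalConfig, only_elemental: bool = True) -> np.ndarray:
    """Centers (mm) of lenslets near the relayed pupil, shape (k, 2).

    With the default ``"hole"`` alignment the optical axis sits at a
    lattice *hole* (a vertex of the honeycomb), putting the three nearest
    lenslets at distance ``pitch/√3`` on an equilateral triangle — the
    arrangement that splits the pupil into three elemental views.
    ``"lenslet"`` alignment centers a lenslet on the axis instead (the
    single-view limit of a very coarse array).  With ``only_elemental``
    the list is restricted to lenslets passing an unvignetted beam: the
    aperture disc lies entirely inside the pupil, or the pupil inside the
    aperture (the custom array masks partially illuminated neighbours to
    suppress stray sub-images).
    """
    p = config.mla_pitch
    rot = config.mla_rotation
    a1 = p * np.array([1.0, 0.0])
    a2 = p * np.array([0.5, np.sqrt(3.0) / 2.0])
    if config.mla_alignment == "hole":
        offset = (a1 + a2) / 3.0   # honeycomb vertex at the origin
    else:
        offset = np.zeros(2)       # lenslet center on the axis
    reach = config.pupil_radius + 2 * p
    m = int(np.ceil(reach / p)) + 2
    ii, jj = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1))
    pts = ii[..., None] * a1 + jj[..., None] * a2 + offset
    pts = pts.reshape(-1, 2)
    c, s = np.cos(rot), np.sin(rot)
    pts = pts @ np.array([[c, s], [-s, c]])
    r = np.hypot(pts[:, 0], pts[:, 1])
    pts = pts[r <= reach]
    if only_elemental:
        r = np.hypot(pts[:, 0], pts[:, 1])
        rp = config.pupil_radius
        inside_pupil = r + p / 2.0 <= rp + 1e-9
        swallows_pupil = r + rp <= p / 2.0 + 1e-9
        pts = pts[inside_pupil | swallows_pupil]
    order = np.lexsort((pts[:, 0], pts[:, 1]))
    return pts[order]


def mla_transmittance(config: OpticalConfig, channel: int = 0,
                      oversample: int = 1,
                      only_elemental: bool = True) -> np.ndarray:
    """Complex transmittance of the MLA on the pupil FFT grid.

    Each lenslet contributes a circular aperture of diameter ``mla_pitch``
    carrying the thin-lens quadratic phase ``exp(−iπ|u−c|²/(λ f_ml))``.
    Warns if the elemental-lenslet count differs from the 3-lens design.
    """
    lam_nm = config.wavelength(channel)
    lam_mm = lam_nm * 1e-6
    ux, uy, _ = _pupil_grid(config, lam_nm, oversample=oversample)
    centers = lenslet_centers(config, only_elemental=only_elemental)
    if only_elemental and len(centers) != 3:
        warnings.warn(
            f"MLA pitch {config.mla_pitch} mm gives {len(centers)} elemental "
            "lenslets inside the pupil, not 3", GeometryWarning)
    t = np.zeros(ux.shape, dtype=np.complex128)
    r_ap = config.mla_pitch / 2.0
    for cx, cy in centers:
        d2 = (ux - cx) ** 2 + (uy - cy) ** 2
        ap = d2 <= r_ap * r_ap
        t[ap] += np.exp(-1j * np.pi * d2[ap] / (lam_mm * config.f_ml))
    return t


def elemental_centers(config: OpticalConfig, units: str = "px") -> np.ndarray:
    """Sensor-plane centers of the elemental images.

    A point at the sample origin images to one spot per elemental lenslet,
    located exactly at the lenslet center projected onto the sensor.  In
    pixel units the result is (row, col) on the computation grid; pairwise
    distances equal ``mla_pitch / pixel_cam`` px.  Warns (and returns all
    intersecting centers) when the geometry is not the 3-lens design.
    """
    centers = lenslet_centers(config, only_elemental=True)
    if len(centers) != 3:
        warnings.warn(
            f"{len(centers)} elemental lenslets (expected 3); returning all",
            GeometryWarning)
    if units == "mm":
        return centers
    if units != "px":
        raise DomainError(f"units must be 'px' or 'mm', got {units!r}")
    n = config.grid_size
    dx_mm = config.pixel_cam * 1e-3
    rows = n // 2 + centers[:, 1] / dx_mm
    cols = n // 2 + centers[:, 0] / dx_mm
    return np.column_stack([rows, cols])


# --------------------------------------------------------------------------
# PSF stack
# --------------------------------------------------------------------------

@dataclass
class PSFStack:
    """System PSF sampled over axial planes.

    ``data`` is a nonnegative float32 array of shape (nz, n, n) on the
    camera pixel grid; ``z_step``/``voxel_xy`` are the axial and lateral
    voxel sizes at sample scale (µm).  Normalised so the z = 0 plane sums
    to 1 (mode ``"z0"``) unless built otherwise.
    """

    data: np.ndarray
    z_step: float          # µm
    voxel_xy: float        # µm
    wavelength: float      # nm
    normalization: str = "z0"

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    @property
    def z_planes(self) -> np.ndarray:
        n = self.n_planes
        return (np.arange(n) - n // 2) * self.z_step

    @property
    def voxel(self) -> tuple:
        """(dz, dy, dx) voxel sizes in µm."""
        return (self.z_step, self.voxel_xy, self.voxel_xy)

    def plane_index(self, z: float) -> int:
        i = int(round(z / self.z_step)) + self.n_planes // 2
        if not 0 <= i < self.n_planes:
            raise DomainError(f"z = {z} µm outside the PSF axial range")
        return i


def min_oversample(config: OpticalConfig, channel: int = 0) -> int:
    """Smallest pixel-integration factor satisfying the pupil band limit.

    The sensor field is band-limited by the pupil; the FFT grid holds it
    only while ``pixel_cam / oversample < λ f_ml / (2 · pupil radius)``.
    1 for the native 6.5 µm camera; 2 when a coarsened desk-scale pitch
    undersamples the shorter emission wavelengths.
    """
    lam_mm = config.wavelength(channel) * 1e-6
    dx_limit = lam_mm * config.f_ml / (2.0 * config.pupil_radius) * 1e3  # µm
    return max(1, int(np.ceil(config.pixel_cam / dx_limit + 1e-9)))


def build_psf_stack(config: OpticalConfig, channel: int = 0,
                    aberration: AberrationMap | None = None,
                    oversample: int | str = "auto",
                    normalization: str = "z0") -> PSFStack:
    """Compute the (hybrid) PSF stack for one emission channel.

    For every axial plane the pupil field is multiplied by the MLA
    transmittance and the Fresnel kernel for one lenslet focal length, and
    a single FFT lands the field on the camera grid; the squared modulus is
    the PSF plane.  With ``oversample > 1`` the field is computed on a
    finer grid and box-binned, i.e. integrated over pixel footprints;
    ``"auto"`` (default) picks the smallest factor that satisfies the
    pupil band limit.  An ``AberrationMap`` adds the calibration phase
    that hybridises the ideal model; passing none (or an all-zero map)
    gives the ideal PSF.
    """
    if oversample == "auto":
        oversample = min_oversample(config, channel)
    if oversample < 1 or int(oversample) != oversample:
        raise ConfigurationError("oversample must be a positive integer or 'auto'")
    oversample = int(oversample)
    lam_nm = config.wavelength(channel)
    lam_mm = lam_nm * 1e-6
    n = config.grid_size
    nos = n * oversample
    ux, uy, _ = _pupil_grid(config, lam_nm, oversample=oversample)
    # MLA with its thin-lens phase, times the free-space Fresnel kernel for
    # one focal length.  Pointwise the two quadratic phases cancel into a
    # per-lenslet tilt, so the product is well sampled even though each
    # factor alone is not.
    t = mla_transmittance(config, channel, oversample=oversample)
    fresnel = np.exp(1j * np.pi * (ux * ux + uy * uy) / (lam_mm * config.f_ml))
    tmla = t * fresnel
    del t, fresnel
    zs = config.z_planes
    out = np.empty((len(zs), n, n), dtype=np.float32)
    for k, z in enumerate(zs):
        pf = pupil_field(config, z, channel, aberration, oversample=oversample)
        fld = _fft.fftshift(_fft.fft2(_fft.ifftshift(pf.amplitude * tmla)))
        inten = (fld.real ** 2 + fld.imag ** 2)
        if oversample > 1:
            inten = inten.reshape(n, oversample, n, oversample).sum(axis=(1, 3))
        out[k] = inten.astype(np.float32)
    if normalization == "z0":
        s0 = float(out[len(zs) // 2].sum())
        if s0 <= 0:
            raise SamplingError("empty in-focus PSF plane; check the sampling")
        out /= s0
    elif normalization == "none":
        pass
    else:
        raise ConfigurationError(f"unknown normalization {normalization!r}")
    return PSFStack(data=out, z_step=config.z_step, voxel_xy=config.voxel_xy,
                    wavelength=lam_nm, normalization=normalization)
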