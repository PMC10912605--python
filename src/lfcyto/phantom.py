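"""Synthetic phantoms and stroboscopic light-field frame rendering.

Ground-truth objects — fluorescent microspheres and simplified cells built
from spheres, spherical shells, puncta and micronuclei sets — are placed in
a hydrodynamically focused flow core, rasterized onto the reconstruction
voxel grid, blurred by the light-field PSF plane by plane, and corrupted
with an sCMOS noise model (Poisson shot noise, Gaussian read noise, fixed
offset).  A frame sequence emulates stroboscopic acquisition: objects
advance along the flow axis between strobes, two-color sequences alternate
emission channels frame by frame, and every frame carries a ground-truth
table of the objects that contributed to it.

Conventions: object centers and offsets are (x, y, z) in µm with x the flow
axis and z the optical axis; voxel arrays are indexed (z, y, x) with the
grid centered on the optical axis.  Rasterized arrays hold fluorophore
*density* (photons per µm³ per strobe); rendering multiplies by the voxel
volume, so summed image counts track object photon totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.fft as _fft
from scipy.ndimage import convolve1d

from .errors import (
    ClippingError,
    ConfigurationError,
    DomainError,
    PhantomWarning,
    ShapeError,
)
from .optics import PSFStack

__all__ = [
    "FlowConfig",
    "NoiseModel",
    "Sphere",
    "Shell",
    "Puncta",
    "Micronuclei",
    "Component",
    "PhantomObject",
    "FrameSequence",
    "make_bead_mixture",
    "make_cell_phantom",
    "voxelize",
    "LightFieldOperator",
    "forward_project",
    "motion_blur_kernel",
    "render_lightfield_frame",
    "simulate_sequence",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowConfig:
    """Microfluidic and stroboscopic timing parameters.

    ``flow_speed`` (mm/s) and ``strobe_duration`` (µs) set the residual
    motion blur per exposure (0.45 µm at the 4.5 mm/s, 100 µs defaults —
    below the lateral resolution, which is what stroboscopic illumination
    is for).  ``t0`` is the global camera exposure (ms), ``t2`` the
    interval between the strobes of one multi-color cycle (µs); the cycle
    period t1 equals the frame period, 1/``frame_rate``.
    """

    flow_speed: float = 4.5          # mm/s
    strobe_duration: float = 100.0   # µs
    frame_rate: float = 200.0        # fps
    t0: float = 5.0                  # ms, global exposure
    t2: float = 200.0                # µs, inter-strobe interval
    core_width: float = 75.0         # µm, hydrodynamic focus width
    channel_depth: float = 30.0      # µm
    objects_per_second: float = 600.0

    def __post_init__(self):
        for name in ("strobe_duration", "frame_rate", "t0", "core_width",
                     "channel_depth"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.flow_speed < 0:
            raise ConfigurationError("flow_speed must be >= 0")
        if self.strobe_duration * 1e-3 > self.t0:
            raise ConfigurationError(
                f"strobe_duration {self.strobe_duration} µs exceeds the "
                f"global exposure t0 = {self.t0} ms")
        if self.t2 * 1e-6 >= self.t1:
            raise ConfigurationError("t2 must be shorter than the frame period")

    @property
    def t1(self) -> float:
        """Multi-illumination cycle period in seconds (= frame period)."""
        return 1.0 / self.frame_rate

    @property
    def blur_length(self) -> float:
        """Motion streak length per strobe, v · τ, in µm."""
        return self.flow_speed * 1e3 * self.strobe_duration * 1e-6


@dataclass
class NoiseModel:
    """sCMOS camera noise: shot noise, read noise and a count offset.

    counts = gain · Poisson(photons) + N(0, read_sigma) + offset

    With ``apply(..., rng)`` under a fixed seed the rendering is
    bit-reproducible; pass ``None`` as the model to render noise-free.
    """

    gain: float = 2.0         # counts per photoelectron
    read_sigma: float = 3.2   # counts
    offset: float = 100.0     # counts
    seed: int | None = None

    def apply(self, photons: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        if rng is None:
            rng = np.random.default_rng(self.seed)
        counts = self.gain * rng.poisson(np.maximum(photons, 0.0)).astype(np.float64)
        if self.read_sigma > 0:
            counts += rng.normal(0.0, self.read_sigma, size=photons.shape)
        return counts + self.offset


# --------------------------------------------------------------------------
# geometry primitives
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Sphere:
    diameter: float  # µm


@dataclass(frozen=True)
class Shell:
    """Spherical shell: outer ``diameter``, radial ``thickness`` inward."""
    diameter: float
    thickness: float


@dataclass(frozen=True)
class Puncta:
    """Set of identical small spheres at ``offsets`` (k, 3) from the center."""
    offsets: tuple
    diameter: float


@dataclass(frozen=True)
class Micronuclei:
    """Nuclear fragments: spheres with individual diameters and offsets."""
    offsets: tuple          # (k, 3) µm, from the component-set centroid
    diameters: tuple        # (k,) µm


@dataclass(frozen=True)
class Component:
    label: str
    geometry: object
    channel: int
    density: float          # photons / µm³ per strobe


def _geometry_spheres(geom, base=np.zeros(3)):
    """Expand a geometry into (center_offset, radius, sign) sphere terms."""
    if isinstance(geom, Sphere):
        return [(base, geom.diameter / 2.0, +1.0)]
    if isinstance(geom, Shell):
        r_out = geom.diameter / 2.0
        r_in = r_out - geom.thickness
        if r_in <= 0:
            return [(base, r_out, +1.0)]
        return [(base, r_out, +1.0), (base, r_in, -1.0)]
    if isinstance(geom, Puncta):
        r = geom.diameter / 2.0
        return [(base + np.asarray(o, float), r, +1.0) for o in geom.offsets]
    if isinstance(geom, Micronuclei):
        return [(base + np.asarray(o, float), d / 2.0, +1.0)
                for o, d in zip(geom.offsets, geom.diameters)]
    raise DomainError(f"unknown geometry {type(geom).__name__}")


def _geometry_volume(geom) -> float:
    return sum(s * 4.0 / 3.0 * np.pi * r ** 3 for _, r, s in _geometry_spheres(geom))


def _geometry_radius(geom) -> float:
    """Bounding radius of a geometry about the object center."""
    return max(float(np.linalg.norm(c)) + r for c, r, s in _geometry_spheres(geom) if s > 0)


@dataclass
class PhantomObject:
    """A ground-truth object: a bead or a simplified cell.

    ``truth`` records the analytic per-object features (volumes, N:C
    ratio, micronuclei dispersion, photon totals...) that the cytometry
    stage is later asked to recover.
    """

    kind: str
    center: np.ndarray                  # (x, y, z) µm
    components: list
    truth: dict = field(default_factory=dict)
    object_id: int | None = None

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        for comp in self.components:
            if comp.density < 0:
                raise DomainError("intensity density must be >= 0")

    @property
    def bounding_radius(self) -> float:
        if not self.components:
            return 0.0
        return max(_geometry_radius(c.geometry) for c in self.components)

    @property
    def channels(self) -> list:
        return sorted({c.channel for c in self.components})

    def total_photons(self, channel: int | None = None) -> float:
        return sum(c.density * _geometry_volume(c.geometry)
                   for c in self.components
                   if channel is None or c.channel == channel)

    def at(self, position) -> "PhantomObject":
        """Copy of the object displaced to ``position``."""
        return PhantomObject(self.kind, np.asarray(position, float),
                             self.components, dict(self.truth), self.object_id)


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def make_bead_mixture(diameters: Sequence[float], counts: Sequence[int],
                      intensity_scale: float = 4.0e5,
                      flow: FlowConfig | None = None,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None,
                      x_span: float = 0.0,
                      z_span: float = 4.0) -> list:
    """Fluorescent microsphere mixture placed uniformly in the flow core.

    ``intensity_scale`` is the fluorophore density in photons/µm³ per
    strobe, identical for every bead, so bead brightness scales with
    volume (d³) as for uniformly dyed microspheres.  Lateral positions are
    uniform over ``|y| ≤ core_width/2``, start positions along the flow
    axis uniform over ``±x_span/2``, axial positions uniform over
    ``±z_span/2``.
    """
    flow = flow or FlowConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    diameters = [float(d) for d in diameters]
    if any(d <= 0 for d in diameters):
        raise DomainError("bead diameters must be > 0")
    if any(d > flow.core_width for d in diameters):
        raise ClippingError("bead larger than the hydrodynamic core width")
    if len(diameters) != len(counts):
        raise DomainError("diameters and counts must have equal length")
    objs = []
    for cls, (d, cnt) in enumerate(zip(diameters, counts)):
        for _ in range(int(cnt)):
            x = rng.uniform(-x_span / 2.0, x_span / 2.0) if x_span > 0 else 0.0
            y = rng.uniform(-flow.core_width / 2.0, flow.core_width / 2.0)
            z = rng.uniform(-z_span / 2.0, z_span / 2.0) if z_span > 0 else 0.0
            vol = np.pi / 6.0 * d ** 3
            obj = PhantomObject(
                kind="bead",
                center=(x, y, z),
                components=[Component("bead", Sphere(d), 0, intensity_scale)],
                truth={"class": cls, "diameter": d, "volume": vol,
                       "photons": intensity_scale * vol},
            )
            objs.append(obj)
    for i, o in enumerate(objs):
        o.object_id = i
    return objs


def _uniform_in_ball(rng, k, radius):
    v = rng.normal(size=(k, 3))
    v /= np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-12)
    r = radius * rng.uniform(size=(k, 1)) ** (1.0 / 3.0)
    return v * r


def make_cell_phantom(kind: str, seed: int | None = None,
                      rng: np.random.Generator | None = None,
                      center=(0.0, 0.0, 0.0), **params) -> PhantomObject:
    """Simplified single-cell phantom with analytic ground truth.

    Kinds
    -----
    ``peroxisome``
        GFP-like puncta (``n_puncta``, ``d_punctum``) scattered in a cell
        of diameter ``d_cell``; channel 0.
    ``membrane_nucleus``
        Membrane shell (``d_cell``, ``membrane_thickness``) on channel 1
        and a solid nucleus (``d_nuc``) on channel 0; truth includes the
        N:C volume ratio (d_nuc/d_cell)³.
    ``two_color_organelle``
        Peroxisome puncta (channel 0) plus mitochondria puncta
        (channel 1).
    ``apoptotic``
        ``k_micronuclei`` nuclear fragments of conserved total volume
        whose mean distance to their common centroid equals
        ``dispersion`` µm (k = 1, dispersion 0 → one intact nucleus),
        with mitochondria puncta on channel 1.
    ``reporter``
        Stained cell body (channel 0) plus a reporter channel (1) whose
        intensity is ``positive_contrast``-fold higher when
        ``positive=True`` — the tdTomato-style expression readout.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    p = params
    d_cell = float(p.get("d_cell", 8.0))
    if d_cell <= 0:
        raise DomainError("d_cell must be > 0")
    comps: list = []
    truth: dict = {"d_cell": d_cell}

    if kind == "peroxisome":
        n = int(p.get("n_puncta", 30))
        dp = float(p.get("d_punctum", 0.4))
        dens = float(p.get("density", 5.0e3))
        offs = _uniform_in_ball(rng, n, max(d_cell / 2.0 - dp, 0.0))
        comps.append(Component("peroxisome", Puncta(tuple(map(tuple, offs)), dp), 0, dens))
        truth.update(n_puncta=n, d_punctum=dp)

    elif kind == "membrane_nucleus":
        d_nuc = float(p.get("d_nuc", 6.57))
        th = float(p.get("membrane_thickness", 0.55))
        if d_nuc >= d_cell:
            raise DomainError("nucleus diameter must be smaller than the cell")
        dens_m = float(p.get("density_membrane", 5.0e3))
        dens_n = float(p.get("density_nucleus", 5.0e3))
        comps.append(Component("membrane", Shell(d_cell, th), 1, dens_m))
        comps.append(Component("nucleus", Sphere(d_nuc), 0, dens_n))
        v_cell = np.pi / 6.0 * d_cell ** 3
        v_nuc = np.pi / 6.0 * d_nuc ** 3
        truth.update(d_nuc=d_nuc, v_cell=v_cell, v_nuc=v_nuc,
                     nc_ratio=(d_nuc / d_cell) ** 3)

    elif kind == "two_color_organelle":
        n_px = int(p.get("n_puncta", 25))
        dp = float(p.get("d_punctum", 0.4))
        n_mito = int(p.get("n_mito", 25))
        dm = float(p.get("d_mito", 0.6))
        dens = float(p.get("density", 5.0e3))
        offs_p = _uniform_in_ball(rng, n_px, max(d_cell / 2.0 - dp, 0.0))
        offs_m = _uniform_in_ball(rng, n_mito, max(d_cell / 2.0 - dm, 0.0))
        comps.append(Component("peroxisome", Puncta(tuple(map(tuple, offs_p)), dp), 0, dens))
        comps.append(Component("mitochondria", Puncta(tuple(map(tuple, offs_m)), dm), 1, dens))
        truth.update(n_puncta=n_px, n_mito=n_mito)

    elif kind == "apoptotic":
        k = int(p.get("k_micronuclei", 1))
        if k < 1:
            raise DomainError("k_micronuclei must be >= 1")
        disp = float(p.get("dispersion", 0.0))
        v_total = float(p.get("v_nuclei_total", np.pi / 6.0 * 5.0 ** 3))
        d_i = (6.0 * v_total / (k * np.pi)) ** (1.0 / 3.0)
        if k == 1 or disp == 0.0:
            offs = np.zeros((k, 3))
        else:
            offs = rng.normal(size=(k, 3))
            offs -= offs.mean(axis=0)
            norms = np.linalg.norm(offs, axis=1)
            offs *= disp / max(norms.mean(), 1e-12)
            # re-center once more; scaling preserves the zero centroid
        if np.any(np.linalg.norm(offs, axis=1) + d_i / 2.0 > d_cell / 2.0):
            raise DomainError("micronuclei do not fit inside the cell; "
                              "reduce dispersion or k")
        dens_n = float(p.get("density_nucleus", 5.0e3))
        comps.append(Component(
            "micronuclei", Micronuclei(tuple(map(tuple, offs)), (d_i,) * k), 0, dens_n))
        n_mito = int(p.get("n_mito", 20))
        if n_mito:
            dm = float(p.get("d_mito", 0.6))
            offs_m = _uniform_in_ball(rng, n_mito, max(d_cell / 2.0 - dm, 0.0))
            comps.append(Component("mitochondria", Puncta(tuple(map(tuple, offs_m)), dm),
                                   1, float(p.get("density_mito", 5.0e3))))
        mean_dist = float(np.mean(np.linalg.norm(offs, axis=1))) if k > 1 else 0.0
        truth.update(k_micronuclei=k, dispersion=disp,
                     micronuclei_mean_distance=mean_dist,
                     micronuclei_mean_volume=v_total / k,
                     apoptotic=k > 1)

    elif kind == "reporter":
        positive = bool(p.get("positive", True))
        contrast = float(p.get("positive_contrast", 10.0))
        dens_stain = float(p.get("density_stain", 5.0e3))
        dens_rep = float(p.get("density_reporter", 2.0e3))
        d_rep = float(p.get("d_reporter", 0.8 * d_cell))
        comps.append(Component("stain", Sphere(d_cell), 0, dens_stain))
        rep_density = dens_rep if positive else dens_rep / contrast
        comps.append(Component("reporter", Sphere(d_rep), 1, rep_density))
        truth.update(positive=positive,
                     reporter_photons=rep_density * np.pi / 6.0 * d_rep ** 3)

    else:
        raise DomainError(f"unknown cell phantom kind {kind!r}")

    obj = PhantomObject(kind=kind, center=center, components=comps, truth=truth)
    return obj


# --------------------------------------------------------------------------
# rasterization
# --------------------------------------------------------------------------

def _axis_coords(n: int, step: float) -> np.ndarray:
    return (np.arange(n) - n // 2) * step


def _add_sphere(vol: np.ndarray, center_xyz, radius: float, density: float,
                voxel: tuple) -> None:
    """Accumulate one sphere with partial-volume (anti-aliased) edges."""
    dz, dy, dx = voxel
    nz, ny, nx = vol.shape
    cx, cy, cz = center_xyz
    if radius < 0.75 * max(voxel):
        # sub-voxel: trilinear splat conserving the analytic volume
        v_sphere = 4.0 / 3.0 * np.pi * radius ** 3
        amount = density * v_sphere / (dz * dy * dx)
        fi = cx / dx + nx // 2
        fj = cy / dy + ny // 2
        fk = cz / dz + nz // 2
        k0, j0, i0 = int(np.floor(fk)), int(np.floor(fj)), int(np.floor(fi))
        wk, wj, wi = fk - k0, fj - j0, fi - i0
        for dk, wz in ((0, 1 - wk), (1, wk)):
            for dj, wy in ((0, 1 - wj), (1, wj)):
                for di, wx in ((0, 1 - wi), (1, wi)):
                    k, j, i = k0 + dk, j0 + dj, i0 + di
                    if 0 <= k < nz and 0 <= j < ny and 0 <= i < nx:
                        vol[k, j, i] += amount * wz * wy * wx
        return
    xs = _axis_coords(nx, dx) - cx
    ys = _axis_coords(ny, dy) - cy
    zs = _axis_coords(nz, dz) - cz
    pad = 1.5 * max(voxel)
    isel = np.nonzero(np.abs(xs) <= radius + pad)[0]
    jsel = np.nonzero(np.abs(ys) <= radius + pad)[0]
    ksel = np.nonzero(np.abs(zs) <= radius + pad)[0]
    if not (len(isel) and len(jsel) and len(ksel)):
        return
    X = xs[isel][None, None, :]
    Y = ys[jsel][None, :, None]
    Z = zs[ksel][:, None, None]
    dist = np.sqrt(X * X + Y * Y + Z * Z)
    safe = np.maximum(dist, 1e-12)
    # local edge width: voxel extent projected on the surface normal
    h = (np.abs(X) * dx + np.abs(Y) * dy + np.abs(Z) * dz) / safe
    h = np.maximum(h, 1e-3 * min(voxel))
    frac = np.clip(0.5 + (radius - dist) / h, 0.0, 1.0)
    vol[np.ix_(ksel, jsel, isel)] += density * frac


def voxelize(obj: PhantomObject, voxel_size, grid_shape,
             clip: bool = False) -> dict:
    """Rasterize a phantom into per-channel 3D density volumes.

    ``voxel_size`` is ``(dz, dy, dx)`` in µm (or a scalar for isotropic
    voxels); ``grid_shape`` is ``(nz, ny, nx)``.  Partial-volume edge
    weighting keeps the integral of density within ~1% of the analytic
    component volume times density; components smaller than a voxel are
    splatted conserving their integral exactly.  Raises
    :class:`ClippingError` when the object sticks out of the grid unless
    ``clip`` is set (flow rendering clips objects at the field edge on
    purpose).  Warns when a feature is smaller than two voxels.
    """
    if np.isscalar(voxel_size):
        voxel = (float(voxel_size),) * 3
    else:
        voxel = tuple(float(v) for v in voxel_size)
    if len(voxel) != 3 or min(voxel) <= 0:
        raise DomainError(f"bad voxel size {voxel_size!r}")
    nz, ny, nx = grid_shape
    out = {}
    half = (nz // 2 * voxel[0], ny // 2 * voxel[1], nx // 2 * voxel[2])
    cx, cy, cz = obj.center
    for comp in obj.components:
        spheres = _geometry_spheres(comp.geometry)
        feature = min(2 * r for _, r, s in spheres if s > 0)
        if feature < 2 * min(voxel):
            warnings.warn(
                f"feature size {feature:.3g} µm below two voxels "
                f"({min(voxel):.3g} µm); integrals are conserved but shapes "
                "are not resolved", PhantomWarning)
        vol = out.setdefault(comp.channel, np.zeros(grid_shape, dtype=np.float64))
        for off, r, sign in spheres:
            c = (cx + off[0], cy + off[1], cz + off[2])
            if not clip:
                if (abs(c[2]) + r > half[0] + voxel[0] / 2 or
                        abs(c[1]) + r > half[1] + voxel[1] / 2 or
                        abs(c[0]) + r > half[2] + voxel[2] / 2):
                    raise ClippingError(
                        f"component {comp.label!r} extends beyond the grid; "
                        "pass clip=True to truncate")
            _add_sphere(vol, c, r, sign * comp.density, voxel)
    for ch in out:
        np.clip(out[ch], 0.0, None, out=out[ch])
    return out


# --------------------------------------------------------------------------
# light-field forward operator
# --------------------------------------------------------------------------

class LightFieldOperator:
    """Linear image-formation operator of the light-field system.

    ``forward`` maps a 3D volume (photons per voxel) to the sensor image:
    each axial plane is convolved with the matching PSF plane and the
    results are summed.  ``adjoint`` is the transpose (per-plane
    correlation), the pairing Richardson-Lucy needs.  ``boundary`` is
    ``"linear"`` (zero-padded linear convolution, cropped back — the
    physical choice) or ``"circular"``.
    """

    def __init__(self, psf: PSFStack, shape: tuple | None = None,
                 boundary: str = "linear", dtype=np.float32):
        self.psf = psf
        self.dtype = np.dtype(dtype)
        cdtype = np.complex64 if self.dtype == np.float32 else np.complex128
        nzp, nyp, nxp = psf.data.shape
        self.shape = tuple(shape) if shape is not None else (nyp, nxp)
        ny, nx = self.shape
        if boundary == "linear":
            sy = _fft.next_fast_len(ny + nyp - 1)
            sx = _fft.next_fast_len(nx + nxp - 1)
        elif boundary == "circular":
            if (ny, nx) != (nyp, nxp):
                raise ShapeError("circular boundary requires frame and PSF "
                                 "planes of equal shape")
            sy, sx = ny, nx
        else:
            raise DomainError(f"boundary must be 'linear' or 'circular', got {boundary!r}")
        self.boundary = boundary
        self.fft_shape = (sy, sx)
        kern = np.zeros((nzp, sy, sx), dtype=self.dtype)
        kern[:, :nyp, :nxp] = psf.data
        kern = np.roll(kern, (-(nyp // 2), -(nxp // 2)), axis=(1, 2))
        self.otf = _fft.rfft2(kern, axes=(1, 2)).astype(cdtype)
        del kern
        self.n_planes = nzp
        self._sens: np.ndarray | None = None

    @property
    def volume_shape(self) -> tuple:
        return (self.n_planes,) + self.shape

    def forward(self, volume: np.ndarray) -> np.ndarray:
        if volume.shape != self.volume_shape:
            raise ShapeError(f"volume shape {volume.shape} does not match "
                             f"operator {self.volume_shape}")
        sy, sx = self.fft_shape
        spec = _fft.rfft2(volume.astype(self.dtype, copy=False),
                          s=(sy, sx), axes=(1, 2))
        spec *= self.otf
        img = _fft.irfft2(spec.sum(axis=0), s=(sy, sx))
        ny, nx = self.shape
        return img[:ny, :nx]

    def adjoint(self, image: np.ndarray) -> np.ndarray:
        if image.shape != self.shape:
            raise ShapeError(f"image shape {image.shape} does not match "
                             f"operator {self.shape}")
        sy, sx = self.fft_shape
        spec = _fft.rfft2(image.astype(self.dtype, copy=False), s=(sy, sx))
        out = _fft.irfft2(spec[None, :, :] * np.conj(self.otf),
                          s=(sy, sx), axes=(1, 2))
        ny, nx = self.shape
        return out[:, :ny, :nx]

    def sensitivity(self) -> np.ndarray:
        """A^T 1 — per-voxel capture efficiency, cached."""
        if self._sens is None:
            self._sens = self.adjoint(np.ones(self.shape, dtype=self.dtype))
        return self._sens


def forward_project(volume: np.ndarray, psf: PSFStack,
                    boundary: str = "linear") -> np.ndarray:
    """Noise-free light-field image of a photons-per-voxel volume."""
    if volume.shape[0] != psf.data.shape[0]:
        raise ShapeError(
            f"volume has {volume.shape[0]} axial planes, PSF has "
            f"{psf.data.shape[0]}")
    op = LightFieldOperator(psf, shape=volume.shape[1:], boundary=boundary)
    return op.forward(volume)


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def motion_blur_kernel(blur_um: float, voxel_x: float) -> np.ndarray:
    """1D box kernel (unit sum) for a streak of ``blur_um`` along the flow axis."""
    if blur_um <= 0:
        return np.ones(1)
    n_px = blur_um / voxel_x
    n = int(np.ceil(n_px))
    if n <= 1:
        # streak shorter than one voxel: spread over two voxels
        w = np.array([0.5, 0.5]) if n_px > 0.999 else np.array([1.0 - n_px / 2, n_px / 2])
        return w / w.sum()
    k = np.ones(n + 1)
    k[0] = k[-1] = 0.5 * (1.0 + n_px - n)
    return k / k.sum()


def render_lightfield_frame(volumes: np.ndarray, psf: PSFStack,
                            flow: FlowConfig | None = None,
                            noise: NoiseModel | None = None,
                            seed: int | None = None,
                            operator: LightFieldOperator | None = None) -> np.ndarray:
    """Render one camera frame from a single-channel density volume.

    Applies motion blur (a line kernel of length flow_speed × strobe
    duration along the flow axis), the per-plane light-field convolution,
    and the sCMOS noise model.  ``volumes`` holds density (photons/µm³);
    returns counts as float64.
    """
    vol = np.asarray(volumes, dtype=np.float64)
    if vol.ndim != 3:
        raise ShapeError("expected a 3D (z, y, x) volume")
    if vol.shape[0] != psf.n_planes:
        raise ShapeError(f"volume has {vol.shape[0]} planes, PSF has {psf.n_planes}")
    dz, dy, dx = psf.voxel
    photons = vol * (dz * dy * dx)
    if flow is not None and flow.blur_length > 0:
        k = motion_blur_kernel(flow.blur_length, dx)
        if len(k) > 1:
            photons = convolve1d(photons, k, axis=2, mode="constant")
    if operator is not None:
        img = operator.forward(photons)
    else:
        img = forward_project(photons, psf)
    np.clip(img, 0.0, None, out=img)
    if noise is None:
        return img
    rng = np.random.default_rng(seed if seed is not None else noise.seed)
    return noise.apply(img, rng)


# --------------------------------------------------------------------------
# sequences
# --------------------------------------------------------------------------

SATURATION = 65535


@dataclass
class FrameSequence:
    """Ordered camera frames with per-frame labels and ground truth.

    ``frames`` are 16-bit counts; ``channels`` and ``timestamps`` give the
    emission channel index and strobe time (s) of every frame;``truth`` is
    one row per (frame, object) occupancy with the object position at the
    strobe.  ``saturated`` flags frames where counts hit the 16-bit
    ceiling (values are clipped, never wrapped).
    """

    frames: np.ndarray
    channels: np.ndarray
    timestamps: np.ndarray
    truth: pd.DataFrame
    voxel: tuple
    saturated: np.ndarray
    objects: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def occupied_frames(self) -> np.ndarray:
        """Frame indices that contain at least one object (ground truth)."""
        if self.truth.empty:
            return np.array([], dtype=int)
        return np.unique(self.truth["frame"].to_numpy())


def _as_psf_per_channel(psf) -> dict:
    if isinstance(psf, PSFStack):
        return {0: psf, 1: psf}
    if isinstance(psf, dict):
        return psf
    return {i: p for i, p in enumerate(psf)}


def simulate_sequence(objects: Sequence[PhantomObject], psf,
                      flow: FlowConfig | None = None,
                      noise: NoiseModel | None = None,
                      n_frames: int = 20,
                      two_color: bool = False,
                      seed: int | None = 0) -> FrameSequence:
    """Simulate a stroboscopic acquisition of objects in flow.

    Objects move along +x at ``flow_speed``; each frame is exposed by one
    strobe whose timestamp samples the object positions.  In two-color
    mode frames strictly alternate channels and the two strobes of a pair
    are separated by ``t2``, so paired frames see almost identical
    positions.  Frames with no object in the field stay blank (noise
    only) and are identifiable from the ground-truth table.
    """
    if n_frames < 1:
        raise DomainError("n_frames must be >= 1")
    flow = flow or FlowConfig()
    psfs = _as_psf_per_channel(psf)
    ref = next(iter(psfs.values()))
    nz = ref.n_planes
    ny, nx = ref.data.shape[1:]
    voxel = ref.voxel
    fov_x = nx * voxel[2]
    fov_y = ny * voxel[1]
    if flow.core_width > fov_y:
        warnings.warn(f"hydrodynamic core ({flow.core_width} µm) wider than "
                      f"the lateral field ({fov_y:.1f} µm)", PhantomWarning)
    master = np.random.default_rng(seed)
    rng_noise = np.random.default_rng(master.integers(2 ** 31))
    for i, o in enumerate(objects):
        if o.object_id is None:
            o.object_id = i
    operators = {ch: LightFieldOperator(p, shape=(ny, nx), boundary="linear")
                 for ch, p in psfs.items()}
    v_um_s = flow.flow_speed * 1e3
    frames = np.zeros((n_frames, ny, nx), dtype=np.uint16)
    channels = np.zeros(n_frames, dtype=int)
    timestamps = np.zeros(n_frames)
    saturated = np.zeros(n_frames, dtype=bool)
    rows = []
    for i in range(n_frames):
        ch = i % 2 if two_color else 0
        if two_color:
            t = (i - i % 2) * flow.t1 + (i % 2) * flow.t2 * 1e-6
        else:
            t = i * flow.t1
        channels[i] = ch
        timestamps[i] = t
        dens = None
        for obj in objects:
            pos = obj.center + np.array([v_um_s * t, 0.0, 0.0])
            if abs(pos[0]) > fov_x / 2.0 + obj.bounding_radius:
                continue
            if ch not in obj.channels:
                continue
            moved = obj.at(pos)
            vols = voxelize(moved, voxel, (nz, ny, nx), clip=True)
            if ch in vols:
                dens = vols[ch] if dens is None else dens + vols[ch]
                rows.append({"frame": i, "object_id": obj.object_id,
                             "kind": obj.kind, "channel": ch,
                             "x": pos[0], "y": pos[1], "z": pos[2],
                             "photons": obj.total_photons(ch)})
        if dens is None:
            img = np.zeros((ny, nx))
            counts = noise.apply(img, rng_noise) if noise is not None else img
        else:
            counts = render_lightfield_frame(
                dens, psfs[ch], flow=flow, noise=None, operator=operators[ch])
            if noise is not None:
                counts = noise.apply(counts, rng_noise)
        if counts.max() > SATURATION:
            saturated[i] = True
        frames[i] = np.clip(np.round(counts), 0, SATURATION).astype(np.uint16)
    truth = pd.DataFrame(
        rows, columns=["frame", "object_id", "kind", "channel",
                       "x", "y", "z", "photons"])
    return FrameSequence(frames=frames, channels=channels,
                         timestamps=timestamps, truth=truth, voxel=voxel,
                         saturated=saturated, objects=list(objects),
                         meta={"two_color": two_color, "seed": seed,
                               "flow": flow, "noise": noise})
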