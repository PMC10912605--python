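"""Processing pipeline: screening, pairing, background, denoising, RLD.

Raw light-field frames go through the stages in acquisition-pipeline
order: blank/debris screening, two-color frame pairing, rolling-ball
background subtraction, variance-stabilised denoising, padding to the PSF
grid, and 3D Richardson-Lucy deconvolution (RLD) against the hybrid PSF.
The forward operator inside RLD is the same per-plane convolve-and-sum
model used to render synthetic frames, so reconstruction is the exact
statistical inverse of the simulator.

Iteration counts follow instrument practice: 30 for microspheres, 50-80
for biological samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import label as _ndlabel
from scipy.ndimage import maximum_filter, minimum_filter
from skimage.restoration import denoise_wavelet

from .errors import (
    ConfigurationError,
    DataError,
    DomainError,
    ParameterError,
    SequenceError,
    ShapeError,
)
from .optics import PSFStack
from .phantom import FrameSequence, LightFieldOperator, NoiseModel

log = logging.getLogger("lfcyto.reconstruct")

__all__ = [
    "PipelineConfig",
    "ReconVolume",
    "screen_frames",
    "pair_color_frames",
    "rolling_ball_background",
    "denoise",
    "pad_to_square",
    "richardson_lucy_3d",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Knobs of the frame-processing pipeline.

    ``screen_threshold`` is a robust z-score on the background-subtracted
    peak; ``max_object_extent`` (px) is the debris rule — frames whose
    largest foreground blob exceeds it are discarded.  ``rl_iterations``
    defaults to the microsphere setting (30); use 50-80 for cells.
    ``pad_target`` defaults to the PSF lateral grid.
    """

    screen_threshold: float = 6.0
    rolling_ball_radius: float = 50.0
    denoiser: str | Callable | None = "stand_in"
    rl_iterations: int = 30
    pad_target: int | None = None
    clip_negative: bool = True
    boundary: str = "linear"
    max_object_extent: float = 200.0   # px
    min_foreground_px: int = 4

    def __post_init__(self):
        if self.rl_iterations < 1:
            raise ConfigurationError("rl_iterations must be >= 1")


@dataclass
class ReconVolume:
    """Reconstructed 3D intensity volume with voxel metadata."""

    data: np.ndarray
    voxel: tuple                      # (dz, dy, dx) µm
    channel: int | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.data < 0):
            raise DataError("reconstructed intensities must be nonnegative")

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel
        return dz * dy * dx


# --------------------------------------------------------------------------
# screening and pairing
# --------------------------------------------------------------------------

def _frame_stats(frame: np.ndarray):
    bg = np.median(frame)
    dev = frame.astype(np.float64) - bg
    mad = np.median(np.abs(dev))
    sigma = 1.4826 * mad + 1e-6
    return dev, sigma


def screen_frames(seq: FrameSequence | np.ndarray,
                  config: PipelineConfig | None = None) -> np.ndarray:
    """Indices of frames that contain a real object.

    A frame is kept when enough pixels rise above ``screen_threshold``
    robust standard deviations over the frame median (blank rejection) and
    the largest connected foreground blob stays below
    ``max_object_extent`` pixels in either direction (debris rejection).
    A zero threshold keeps everything.  An empty keep-set is a valid
    outcome.
    """
    config = config or PipelineConfig()
    frames = seq.frames if isinstance(seq, FrameSequence) else np.asarray(seq)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise DataError("expected a non-empty (n, rows, cols) frame stack")
    keep = []
    for i, frame in enumerate(frames):
        if config.screen_threshold <= 0:
            keep.append(i)
            continue
        dev, sigma = _frame_stats(frame)
        fg = dev > config.screen_threshold * sigma
        n_fg = int(fg.sum())
        if n_fg < config.min_foreground_px:
            log.debug("frame %d screened out: blank", i)
            continue
        labels, n_lab = _ndlabel(fg)
        debris = False
        for lab in range(1, n_lab + 1):
            ys, xs = np.nonzero(labels == lab)
            if (ys.max() - ys.min() + 1 > config.max_object_extent or
                    xs.max() - xs.min() + 1 > config.max_object_extent):
                debris = True
                break
        if debris:
            log.debug("frame %d screened out: debris-sized blob", i)
            continue
        keep.append(i)
    return np.asarray(keep, dtype=int)


def pair_color_frames(seq: FrameSequence,
                      indices: Sequence[int] | None = None) -> list:
    """Pair adjacent opposite-channel frames of an alternating sequence.

    Returns ``(index_A, index_B)`` tuples of original frame indices.  The
    two strobes of one illumination cycle land on frames (2k, 2k+1), so
    only cycle-aligned neighbours are paired — an odd frame and the next
    even frame are a full frame period apart and would mis-register the
    channels.  An unpaired trailing frame is dropped with a log entry.
    Raises :class:`SequenceError` when the labels do not alternate.
    """
    ch = np.asarray(seq.channels)
    if len(ch) >= 2 and np.any(ch[1:] == ch[:-1]):
        raise SequenceError("channel labels do not alternate strictly")
    if indices is None:
        indices = np.arange(len(ch))
    indices = list(indices)
    pairs = []
    k = 0
    while k < len(indices) - 1:
        i, j = indices[k], indices[k + 1]
        if j == i + 1 and i % 2 == 0 and ch[i] != ch[j]:
            pairs.append((i, j))
            k += 2
        else:
            log.info("frame %d left unpaired (partner missing)", i)
            k += 1
    if k == len(indices) - 1:
        log.info("trailing frame %d dropped (no partner)", indices[-1])
    return pairs


# --------------------------------------------------------------------------
# per-frame conditioning
# --------------------------------------------------------------------------

def rolling_ball_background(image: np.ndarray, radius: float) -> np.ndarray:
    """Subtract a grayscale-morphology background estimate.

    The background is the morphological opening of the image with a
    ``(2·radius+1)``-pixel structuring element (the separable fast variant
    of the classic rolling-ball estimate); the result is clipped at zero.
    ``radius`` must exceed the feature radius, otherwise real signal is
    eaten into the background.
    """
    if radius <= 0:
        raise ParameterError("rolling-ball radius must be > 0")
    img = np.asarray(image, dtype=np.float64)
    size = 2 * int(radius) + 1
    background = maximum_filter(minimum_filter(img, size=size), size=size)
    return np.clip(img - background, 0.0, None)


def _anscombe(x):
    return 2.0 * np.sqrt(np.maximum(x, 0.0) + 3.0 / 8.0)


def _anscombe_inv(y):
    return np.maximum(y / 2.0, 0.0) ** 2 - 3.0 / 8.0


def denoise(image: np.ndarray, noise: NoiseModel | None = None,
            method: str | Callable | None = "stand_in") -> np.ndarray:
    """Denoising stage with a pluggable backend.

    The built-in stand-in applies a variance-stabilising (Anscombe)
    transform using the camera gain/offset when a :class:`NoiseModel` is
    supplied, then wavelet coefficient shrinkage (BayesShrink), then the
    inverse transform.  It boosts peak SNR on shot-noise-limited frames
    without displacing object centroids.  Pass a callable for a plug-in
    denoiser, ``None`` or ``"none"`` to disable.
    """
    img = np.asarray(image, dtype=np.float64)
    if method is None or method == "none":
        return img
    if callable(method):
        return np.asarray(method(img), dtype=np.float64)
    if method != "stand_in":
        raise ParameterError(f"unknown denoiser {method!r}")
    if noise is not None:
        photons = (img - noise.offset) / max(noise.gain, 1e-12)
    else:
        photons = img
    t = _anscombe(photons)
    scale = max(t.max(), 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        den = denoise_wavelet(t / scale, method="BayesShrink", mode="soft",
                              wavelet="db2", rescale_sigma=True)
    out = _anscombe_inv(den * scale)
    if noise is not None:
        out = out * noise.gain + noise.offset
    return out


def pad_to_square(image: np.ndarray, target: int,
                  return_slices: bool = False):
    """Zero-pad a frame to ``target × target`` px, content centered.

    The inverse crop (as slices) can be returned for provenance.  Total
    intensity is preserved exactly.
    """
    img = np.asarray(image)
    ny, nx = img.shape
    if target < ny or target < nx:
        raise ParameterError(
            f"pad target {target} smaller than the image {img.shape}")
    py, px = (target - ny) // 2, (target - nx) // 2
    out = np.zeros((target, target), dtype=img.dtype)
    out[py:py + ny, px:px + nx] = img
    if return_slices:
        return out, (slice(py, py + ny), slice(px, px + nx))
    return out


# --------------------------------------------------------------------------
# Richardson-Lucy deconvolution
# --------------------------------------------------------------------------

def richardson_lucy_3d(frame: np.ndarray, psf: PSFStack,
                       iterations: int = 30,
                       boundary: str = "linear",
                       operator: LightFieldOperator | None = None,
                       eps_factor: float = 1e-12,
                       channel: int | None = None) -> ReconVolume:
    """3D Richardson-Lucy deconvolution of one light-field frame.

    Runs the multiplicative maximum-likelihood update

        x ← x · Aᵀ(y / (A x)) / Aᵀ1

    where A is the per-plane convolve-and-sum light-field operator.  The
    estimate starts uniform and positive, divisions are guarded by
    ``eps_factor · max(y)``, and the output is nonnegative by
    construction.  Deterministic — no random state is involved.
    """
    if iterations < 1:
        raise DomainError("iterations must be >= 1")
    y = np.asarray(frame, dtype=np.float64)
    if y.ndim != 2:
        raise DataError("expected a 2D frame")
    if np.any(~np.isfinite(y)) or np.any(y < 0):
        raise DataError("frame contains NaN/inf or negative counts")
    if operator is None:
        operator = LightFieldOperator(psf, shape=y.shape, boundary=boundary)
    elif operator.shape != y.shape:
        raise ShapeError("operator shape does not match the frame")
    prov = {"iterations": iterations, "boundary": operator.boundary,
            "psf_planes": psf.n_planes, "wavelength": psf.wavelength}
    if y.max() <= 0:
        warnings.warn("all-zero frame; returning an empty volume")
        return ReconVolume(np.zeros(operator.volume_shape, dtype=np.float32),
                           psf.voxel, channel, prov)
    eps = eps_factor * y.max()
    sens = operator.sensitivity()
    sens_safe = np.maximum(sens, 1e-6 * sens.max())
    x = np.full(operator.volume_shape,
                y.sum() / np.prod(operator.volume_shape),
                dtype=operator.dtype)
    y = y.astype(operator.dtype)
    for _ in range(iterations):
        est = operator.forward(x)
        ratio = y / np.maximum(est, eps)
        x *= operator.adjoint(ratio) / sens_safe
    np.clip(x, 0.0, None, out=x)
    return ReconVolume(x.astype(np.float32), psf.voxel, channel, prov)


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def run_pipeline(seq: FrameSequence, psf,
                 config: PipelineConfig | None = None) -> tuple:
    """Run screen → (pair) → background → denoise → pad → RLD.

    ``psf`` is a :class:`PSFStack` or a channel-indexed dict of stacks.
    Returns ``(volumes, provenance)`` where ``volumes`` is a list of
    :class:`ReconVolume` (one per kept frame, or two per kept two-color
    pair) and ``provenance`` records every stage decision.
    """
    from .phantom import _as_psf_per_channel
    config = config or PipelineConfig()
    psfs = _as_psf_per_channel(psf)
    noise = seq.meta.get("noise") if isinstance(seq.meta, dict) else None
    keep = screen_frames(seq, config)
    provenance = {"screen": {"kept": keep.tolist(),
                             "threshold": config.screen_threshold},
                  "frames": []}
    two_color = bool(seq.meta.get("two_color")) if isinstance(seq.meta, dict) else False
    if two_color:
        pairs = pair_color_frames(seq, keep)
        jobs = [i for pair in pairs for i in pair]
        provenance["pairs"] = pairs
    else:
        jobs = list(keep)
    ref = next(iter(psfs.values()))
    target = config.pad_target or ref.data.shape[-1]
    operators: dict = {}
    volumes = []
    # the rolling-ball stage removes the camera offset along with the
    # background, so the denoiser must not subtract it again
    if noise is not None:
        from dataclasses import replace as _dc_replace
        noise = _dc_replace(noise, offset=0.0)
    for i in jobs:
        ch = int(seq.channels[i])
        frame = seq.frames[i].astype(np.float64)
        frame = rolling_ball_background(frame, config.rolling_ball_radius)
        frame = denoise(frame, noise=noise, method=config.denoiser)
        # clipping negatives leaves a small positive bias in the empty
        # background; remove the residual pedestal so deconvolution does
        # not redistribute it into ghost structure
        frame -= np.median(frame)
        if config.clip_negative:
            np.clip(frame, 0.0, None, out=frame)
        frame, crop = pad_to_square(frame, target, return_slices=True)
        if ch not in operators:
            operators[ch] = LightFieldOperator(
                psfs[ch], shape=frame.shape, boundary=config.boundary)
        vol = richardson_lucy_3d(frame, psfs[ch], config.rl_iterations,
                                 operator=operators[ch], channel=ch)
        vol.provenance.update(frame=i, channel=ch,
                              crop=[[s.start, s.stop] for s in crop],
                              stages=["rolling_ball",
                                      str(config.denoiser), "pad", "rld"])
        provenance["frames"].append(vol.provenance)
        volumes.append(vol)
    return volumes, provenance
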