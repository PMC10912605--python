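"""Formats, configuration and provenance.

Frames travel as multipage 16-bit grayscale TIFF (both 1024×1024 and
1024×900 camera crops are accepted); PSF stacks and reconstructed volumes
as multipage 32-bit float TIFF with voxel-size metadata in the TIFF
description tag (JSON); feature tables as CSV; configuration as a flat
key-value text file with dotted namespaces (YAML-style); provenance as
JSON with a complete chain from every output back to raw input or
generator seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigurationError, DataError
from .optics import OpticalConfig, PSFStack
from .phantom import FlowConfig, FrameSequence, NoiseModel
from .reconstruct import PipelineConfig, ReconVolume

__all__ = [
    "RunConfig",
    "ProvenanceLog",
    "read_frames",
    "write_frames",
    "read_psf",
    "write_psf",
    "read_volume",
    "write_volume",
    "read_config",
    "write_config",
]

_VERSION = "0.1.0"


def _jsonable(o):
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


# --------------------------------------------------------------------------
# TIFF frames
# --------------------------------------------------------------------------

def write_frames(path, seq: FrameSequence) -> None:
    """Write a frame sequence as multipage 16-bit TIFF + ground-truth sidecar.

    Channel labels, timestamps and voxel sizes go into the TIFF
    description; the ground-truth table goes next to the stack as
    ``<stem>_truth.csv``.
    """
    path = Path(path)
    desc = json.dumps({
        "channels": np.asarray(seq.channels).tolist(),
        "timestamps": np.asarray(seq.timestamps).tolist(),
        "voxel": list(seq.voxel),
        "saturated": np.asarray(seq.saturated).astype(int).tolist(),
        "two_color": bool(seq.meta.get("two_color", False)),
    }, default=_jsonable)
    tifffile.imwrite(path, seq.frames, description=desc,
                     photometric="minisblack")
    seq.truth.to_csv(path.with_name(path.stem + "_truth.csv"), index=False)


def read_frames(path) -> FrameSequence:
    """Read a multipage 8/16-bit grayscale TIFF as a frame sequence.

    Page order is preserved.  1024×900 pages are accepted and flagged in
    ``meta['needs_padding']`` for the padding stage.  RGB or float input
    raises :class:`DataError`.  A ``<stem>_truth.csv`` sidecar is loaded
    when present.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            if tf.pages[0].samplesperpixel > 1:
                raise DataError("RGB/multisample TIFF is not raw camera data; "
                                "expected grayscale pages")
            data = tf.asarray()
            desc = tf.pages[0].description
    except (tifffile.TiffFileError, FileNotFoundError) as exc:
        raise DataError(f"cannot read TIFF {path}: {exc}") from None
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise DataError(f"expected grayscale pages, got shape {data.shape}")
    if data.dtype.kind == "f":
        raise DataError("float frames are not raw camera data; expected 8/16-bit")
    if data.dtype.kind not in "u" or data.dtype.itemsize > 2:
        raise DataError(f"unsupported dtype {data.dtype}; expected uint8/uint16")
    meta = {}
    channels = np.zeros(len(data), dtype=int)
    timestamps = np.arange(len(data), dtype=float)
    voxel = (0.1, 0.0, 0.0)
    saturated = np.zeros(len(data), dtype=bool)
    if desc:
        try:
            d = json.loads(desc)
            channels = np.asarray(d.get("channels", channels), dtype=int)
            timestamps = np.asarray(d.get("timestamps", timestamps), dtype=float)
            voxel = tuple(d.get("voxel", voxel))
            saturated = np.asarray(d.get("saturated", saturated), dtype=bool)
            meta["two_color"] = bool(d.get("two_color", False))
        except (json.JSONDecodeError, TypeError):
            pass
    if data.shape[1] != data.shape[2]:
        meta["needs_padding"] = True
    sidecar = path.with_name(path.stem + "_truth.csv")
    truth = pd.read_csv(sidecar) if sidecar.exists() else pd.DataFrame(
        columns=["frame", "object_id", "kind", "channel", "x", "y", "z", "photons"])
    return FrameSequence(frames=data.astype(np.uint16), channels=channels,
                         timestamps=timestamps, truth=truth, voxel=voxel,
                         saturated=saturated, meta=meta)


# --------------------------------------------------------------------------
# PSF stacks and volumes
# --------------------------------------------------------------------------

def write_psf(path, psf: PSFStack) -> None:
    desc = json.dumps({"z_step": psf.z_step, "voxel_xy": psf.voxel_xy,
                       "wavelength": psf.wavelength,
                       "normalization": psf.normalization})
    tifffile.imwrite(path, psf.data.astype(np.float32), description=desc,
                     photometric="minisblack")


def read_psf(path) -> PSFStack:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(np.float32)
        desc = tf.pages[0].description
    try:
        d = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        raise DataError(f"{path} lacks PSF voxel metadata") from None
    return PSFStack(data=data, z_step=float(d["z_step"]),
                    voxel_xy=float(d["voxel_xy"]),
                    wavelength=float(d["wavelength"]),
                    normalization=d.get("normalization", "z0"))


def write_volume(path, vol: ReconVolume) -> None:
    desc = json.dumps({"voxel": list(vol.voxel), "channel": vol.channel,
                       "provenance": vol.provenance}, default=_jsonable)
    tifffile.imwrite(path, vol.data.astype(np.float32), description=desc,
                     photometric="minisblack")


def read_volume(path) -> ReconVolume:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(np.float32)
        desc = tf.pages[0].description
    try:
        d = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        raise DataError(f"{path} lacks volume voxel metadata") from None
    return ReconVolume(data=data, voxel=tuple(d["voxel"]),
                       channel=d.get("channel"),
                       provenance=d.get("provenance", {}))


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

_SECTIONS = {"optics": OpticalConfig, "flow": FlowConfig,
             "pipeline": PipelineConfig, "noise": NoiseModel}

_TUPLE_FIELDS = {"wavelengths", "sensor_shape"}


@dataclass
class RunConfig:
    """Everything one run needs: sub-configs, paths, seed, log level."""

    optics: OpticalConfig = field(default_factory=OpticalConfig)
    flow: FlowConfig = field(default_factory=FlowConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    noise: NoiseModel | None = field(default_factory=NoiseModel)
    paths: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    def check_paths(self) -> None:
        for key, p in self.paths.items():
            if key.startswith("in_") and not Path(p).exists():
                raise ConfigurationError(f"input path {key} = {p} does not exist")

    def flat(self) -> dict:
        out = {"seed": self.seed, "log_level": self.log_level}
        for sec in _SECTIONS:
            obj = getattr(self, sec)
            if obj is None:
                continue
            for k, v in vars(obj).items():
                if k.startswith("_"):
                    continue
                if isinstance(v, tuple):
                    v = list(v)
                if isinstance(v, (int, float, str, bool, list)) or v is None:
                    out[f"{sec}.{k}"] = v
        for k, v in self.paths.items():
            out[f"paths.{k}"] = str(v)
        return out


def read_config(path) -> RunConfig:
    """Parse a flat dotted-key YAML config into a :class:`RunConfig`.

    Example::

        optics.na: 1.45
        optics.sensor_shape: [512, 512]
        flow.flow_speed: 4.5
        pipeline.rl_iterations: 30
        seed: 7
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path} is not a flat key-value mapping")
    sections = {name: {} for name in _SECTIONS}
    top = {}
    paths = {}
    for key, val in raw.items():
        if "." in str(key):
            sec, _, fld = str(key).partition(".")
            if sec == "paths":
                paths[fld] = val
            elif sec in sections:
                if fld in _TUPLE_FIELDS and isinstance(val, list):
                    val = tuple(val)
                sections[sec][fld] = val
            else:
                raise ConfigurationError(f"unknown config section {sec!r}")
        else:
            top[str(key)] = val
    try:
        cfg = RunConfig(
            optics=OpticalConfig(**sections["optics"]),
            flow=FlowConfig(**sections["flow"]),
            pipeline=PipelineConfig(**sections["pipeline"]),
            noise=NoiseModel(**sections["noise"]),
            paths=paths,
            seed=int(top.get("seed", 0)),
            log_level=str(top.get("log_level", "INFO")),
        )
    except TypeError as exc:
        raise ConfigurationError(f"bad config key: {exc}") from None
    return cfg


def write_config(path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.flat(), fh, default_flow_style=None, sort_keys=True)


# --------------------------------------------------------------------------
# provenance
# --------------------------------------------------------------------------

class ProvenanceLog:
    """Per-stage processing log chaining outputs back to inputs."""

    def __init__(self, seed: int | None = None):
        self.entries: list = []
        self.seed = seed

    def add(self, stage: str, params: dict | None = None,
            inputs=None, outputs=None) -> dict:
        entry = {
            "stage": stage,
            "params": params or {},
            "inputs": [str(i) for i in (inputs or [])],
            "outputs": [str(o) for o in (outputs or [])],
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "version": _VERSION,
        }
        if self.seed is not None:
            entry["seed"] = self.seed
        self.entries.append(entry)
        return entry

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "entries": self.entries}, fh, indent=2, default=_jsonable)
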