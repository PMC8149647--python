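"""Image I/O, sensor preprocessing, and configuration files.

Results are exchanged as 32-bit float TIFFs with optical metadata in sidecar
YAML; raw sensor captures are 16-bit integer arrays (10-bit data), either an
RGB frame or a Bayer mosaic that is demosaiced here.  Only the green channel
is used downstream — it is the sharpest channel for a 532 nm source on an
RGGB sensor.

Conventions: pixel coordinates are 0-based, row-major, origin at the top
left; crops are origin + size.  Wavelengths are nanometres, distances and
pitch micrometres, enforced at config parse.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import tifffile
import yaml

from .baselines import HologramStack
from .wave_optics import Hologram, PropagationSettings

__all__ = [
    "RawCapture",
    "save_image",
    "load_image",
    "save_settings",
    "load_settings",
    "save_decoder_config",
    "load_decoder_config",
    "preprocess",
    "demosaic_green",
    "load_stack_manifest",
    "save_loss_history",
]

SENSOR_PITCH_UM = 1.12
CROP_SIZE = 512


@dataclass
class RawCapture:
    """A raw sensor frame: Bayer mosaic (2-D) or demosaiced RGB (3-D)."""

    data: np.ndarray
    bit_depth: int = 10
    pitch_um: float = SENSOR_PITCH_UM
    bayer_pattern: str = "RGGB"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError("raw capture must be a 2-D mosaic or a 3-D RGB frame")
        if self.data.ndim == 3 and self.data.shape[2] != 3:
            raise ValueError("RGB frame must have 3 channels last")


def save_image(path: Union[str, Path], image: np.ndarray) -> None:
    """Write a 2-D array as 32-bit float TIFF."""
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def load_image(path: Union[str, Path]) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=np.float64)


def save_settings(path: Union[str, Path], settings: PropagationSettings) -> None:
    payload = {
        "wavelength_nm": float(settings.wavelength_nm),
        "distance_um": float(settings.distance_um),
        "pitch_um": float(settings.pitch_um),
        "evanescent_policy": settings.evanescent_policy,
        "pad_factor": int(settings.pad_factor),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_settings(path: Union[str, Path]) -> PropagationSettings:
    payload = yaml.safe_load(Path(path).read_text())
    for key in ("wavelength_nm", "distance_um", "pitch_um"):
        if key not in payload:
            raise ValueError(f"optics config is missing {key!r} (units are nm / um)")
    return PropagationSettings(
        wavelength_nm=float(payload["wavelength_nm"]),
        distance_um=float(payload["distance_um"]),
        pitch_um=float(payload["pitch_um"]),
        evanescent_policy=payload.get("evanescent_policy", "zero"),
        pad_factor=int(payload.get("pad_factor", 1)),
    )


def save_decoder_config(path: Union[str, Path], config) -> None:
    """Network shape as YAML (depth, channels, input size, output channels)."""
    payload = {
        "depth": config.depth,
        "channels": list(config.channels),
        "input_size": config.input_size,
        "upsample": config.upsample,
        "output_channels": config.output_channels,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_decoder_config(path: Union[str, Path]):
    from .decoder import DecoderConfig

    payload = yaml.safe_load(Path(path).read_text())
    return DecoderConfig(
        depth=int(payload["depth"]),
        channels=tuple(int(k) for k in payload["channels"]),
        input_size=int(payload["input_size"]),
        upsample=int(payload.get("upsample", 2)),
        output_channels=int(payload.get("output_channels", 2)),
    )


def demosaic_green(mosaic: np.ndarray, pattern: str = "RGGB") -> np.ndarray:
    """Bilinear interpolation of the green channel from a Bayer mosaic.

    Green sites keep their measured value; red/blue sites take the mean of
    their (edge-clamped) 4-neighborhood green samples.
    """
    mosaic = np.asarray(mosaic, dtype=np.float64)
    if pattern not in ("RGGB", "BGGR", "GRBG", "GBRG"):
        raise ValueError(f"unsupported Bayer pattern {pattern!r}")
    ny, nx = mosaic.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    if pattern in ("RGGB", "BGGR"):
        green_mask = (yy + xx) % 2 == 1
    else:
        green_mask = (yy + xx) % 2 == 0
    padded = np.pad(mosaic, 1, mode="edge")
    neighbors = (
        padded[:-2, 1:-1] + padded[2:, 1:-1] + padded[1:-1, :-2] + padded[1:-1, 2:]
    ) / 4.0
    return np.where(green_mask, mosaic, neighbors)


def preprocess(
    raw: RawCapture,
    settings: PropagationSettings,
    background: Optional[np.ndarray] = None,
    crop_origin: Tuple[int, int] = (0, 0),
    crop_size: int = CROP_SIZE,
) -> Hologram:
    """Raw capture -> normalized hologram.

    Demosaics (if needed), takes the green channel, crops ``crop_size`` from
    ``crop_origin`` (row, col), and divides by the background over the same
    crop; without a background the crop is divided by its own mean so the
    free-space level sits near 1.  Zero-valued background pixels are guarded
    (division skipped there) and their count reported.
    """
    if raw.data.ndim == 3:
        green = np.asarray(raw.data[:, :, 1], dtype=np.float64)
    else:
        green = demosaic_green(raw.data, raw.bayer_pattern)
    r0, c0 = crop_origin
    if r0 < 0 or c0 < 0 or r0 + crop_size > green.shape[0] or c0 + crop_size > green.shape[1]:
        raise ValueError(
            f"crop {crop_size} at {crop_origin} exceeds the {green.shape} frame"
        )
    crop = green[r0 : r0 + crop_size, c0 : c0 + crop_size]
    if background is not None:
        background = np.asarray(background, dtype=np.float64)
        if background.ndim == 3:
            background = background[:, :, 1]
        if background.shape == green.shape:
            background = background[r0 : r0 + crop_size, c0 : c0 + crop_size]
        elif background.shape != crop.shape:
            raise ValueError(
                f"background {background.shape} matches neither the frame nor the crop"
            )
        zeros = int(np.count_nonzero(background <= 0))
        if zeros:
            import warnings

            warnings.warn(f"{zeros} non-positive background pixels; division guarded there")
        safe = np.where(background > 0, background, 1.0)
        intensity = crop / safe
    else:
        mean = float(crop.mean())
        if mean <= 0:
            raise ValueError("cannot normalize an all-zero crop")
        intensity = crop / mean
    return Hologram(np.clip(intensity, 0.0, None), settings)


def load_stack_manifest(path: Union[str, Path]) -> HologramStack:
    """Read a multi-height stack: YAML listing per-plane image path + distance.

    Format::

        wavelength_nm: 532.2
        pitch_um: 1.12
        planes:
          - {path: plane0.tif, distance_um: 300.0}
          - {path: plane1.tif, distance_um: 350.0}
    """
    path = Path(path)
    payload = yaml.safe_load(path.read_text())
    wavelength = float(payload["wavelength_nm"])
    pitch = float(payload["pitch_um"])
    holograms, distances = [], []
    for plane in payload["planes"]:
        z = float(plane["distance_um"])
        settings = PropagationSettings(wavelength_nm=wavelength, distance_um=z, pitch_um=pitch)
        image = load_image(path.parent / plane["path"])
        holograms.append(Hologram(image, settings))
        distances.append(z)
    return HologramStack(holograms=holograms, distances_um=distances)


def save_loss_history(path: Union[str, Path], losses: np.ndarray) -> None:
    """Loss trace as a two-column CSV (iteration, loss)."""
    with open(path, "w") as f:
        f.write("iteration,loss\n")
        for i, value in enumerate(np.asarray(losses)):
            f.write(f"{i},{value!r}\n")
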