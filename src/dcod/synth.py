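"""Synthetic objects and holograms for testing the full reconstruction stack.

Generates thin transparent phantoms (phase in [0, 2*pi), amplitude in [0, 1])
and simulates their in-line holograms under coherent plane-wave illumination
at the reference optical geometry: 532.2 nm wavelength, object plane 300 um
from the sensor, 1.12 um pixel pitch, and 50 um spacing for multi-height
stacks.  Every generator is a pure function of its parameters and seed.

Phantom phase excursions are kept <= pi by default: with larger excursions
the wrapped-phase ambiguity (which no method here attempts to resolve)
dominates reconstruction error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy import ndimage

from .baselines import HologramStack
from .wave_optics import Hologram, ObjectField, PropagationSettings, hologram_intensity

__all__ = [
    "SimulationSettings",
    "make_phantom",
    "simulate_hologram",
    "blur_series",
    "contrast_series",
    "multi_height_stack",
]


@dataclass(frozen=True)
class SimulationSettings:
    """Reference optical geometry for simulated experiments."""

    wavelength_nm: float = 532.2
    distance_um: float = 300.0
    pitch_um: float = 1.12
    stack_spacing_um: float = 50.0
    plane_count: int = 6

    def __post_init__(self) -> None:
        if min(self.wavelength_nm, self.distance_um, self.pitch_um, self.stack_spacing_um) <= 0:
            raise ValueError("all simulation lengths must be positive")

    def propagation(self, pad_factor: int = 2) -> PropagationSettings:
        return PropagationSettings(
            wavelength_nm=self.wavelength_nm,
            distance_um=self.distance_um,
            pitch_um=self.pitch_um,
            pad_factor=pad_factor,
        )


def _smooth_bumps(size: int, rng: np.random.Generator, n_bumps: int, sigma_frac: float) -> np.ndarray:
    """Sum of Gaussian bumps with random centers/widths, normalized to [0, 1]."""
    y, x = np.mgrid[0:size, 0:size]
    img = np.zeros((size, size), dtype=np.float64)
    for _ in range(n_bumps):
        cy, cx = rng.uniform(0.15 * size, 0.85 * size, size=2)
        s = rng.uniform(0.5, 1.5) * sigma_frac * size
        img += np.exp(-(((y - cy) ** 2 + (x - cx) ** 2) / (2 * s**2)))
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    return img


def make_phantom(kind: str, size: int = 64, seed: int = 0, pitch_um: float = 1.12) -> ObjectField:
    """Deterministic test object of the requested kind.

    Kinds
    -----
    ``blobs``
        Smooth cell-like phase bumps with spatially correlated amplitude
        dips — mimics unstained cells (phase-dominant, mild absorption).
    ``bars`` / ``grating``
        Periodic line pairs (period 8 px for ``bars``, 4 px for ``grating``).
    ``usaf_like``
        Isolated three-bar groups at decreasing scales, resolution-target
        style.
    """
    if size < 32 or (size & (size - 1)) != 0:
        raise ValueError("size must be a power of two >= 32")
    rng = np.random.default_rng(seed)
    if kind == "blobs":
        bumps = _smooth_bumps(size, rng, n_bumps=6, sigma_frac=0.06)
        phase = np.pi * bumps  # excursion <= pi, avoids wrapped-phase failure
        amplitude = 1.0 - 0.4 * _smooth_bumps(size, rng, n_bumps=4, sigma_frac=0.08) - 0.1 * bumps
        amplitude = np.clip(amplitude, 0.0, 1.0)
    elif kind in ("bars", "grating"):
        period = 8 if kind == "bars" else 4
        x = np.arange(size)
        line = 0.5 * (1.0 + np.sign(np.sin(2 * np.pi * x / period)))
        amplitude = np.clip(0.3 + 0.7 * np.tile(line, (size, 1)), 0.0, 1.0)
        phase = np.full((size, size), 0.25 * np.pi) * np.tile(line, (size, 1))
    elif kind == "usaf_like":
        amplitude = np.ones((size, size), dtype=np.float64)
        phase = np.zeros((size, size), dtype=np.float64)
        bar_w = max(size // 16, 2)
        origin = size // 8
        for group in range(3):
            w = max(bar_w >> group, 1)
            y0 = origin + group * 5 * bar_w
            for k in range(3):
                x0 = origin + k * 2 * w
                amplitude[y0 : y0 + 4 * w, x0 : x0 + w] = 0.1
                phase[y0 : y0 + 4 * w, x0 : x0 + w] = 0.5 * np.pi
    else:
        raise ValueError(f"unknown phantom kind: {kind!r}")
    phase = np.mod(phase, 2.0 * np.pi)
    return ObjectField(phase=phase, amplitude=amplitude, pitch_um=pitch_um)


def simulate_hologram(
    obj: ObjectField,
    sim: SimulationSettings = SimulationSettings(),
    noise_std: float = 0.0,
    seed: int = 0,
) -> Hologram:
    """Forward-simulate the in-line hologram of ``obj`` at the sensor plane.

    Propagation uses 2x edge padding to suppress periodic wraparound, then
    crops back.  Optional additive Gaussian detection noise is clipped at 0.
    """
    if noise_std < 0:
        raise ValueError("noise_std must be nonnegative")
    settings = sim.propagation(pad_factor=2)
    holo = hologram_intensity(obj, settings)
    intensity = holo.intensity
    if noise_std > 0:
        rng = np.random.default_rng(seed)
        intensity = np.clip(intensity + rng.normal(0.0, noise_std, intensity.shape), 0.0, None)
    # the solver itself runs unpadded, as on cropped real captures
    return Hologram(intensity, sim.propagation(pad_factor=1))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def blur_series(amplitude: np.ndarray, sigmas: Sequence[float] = (0.0, 1.0, np.e, np.e**2, np.e**3)) -> List[np.ndarray]:
    """Gaussian blur ladder: sigma = 0, e^0, e^1, e^2, e^3.

    Kernel support follows ``d(sigma) = 6*round(sigma) + 1`` (round half-up),
    applied as a truncated Gaussian with reflective borders.  Element 0 is
    the unblurred image.
    """
    amplitude = np.asarray(amplitude, dtype=np.float64)
    out: List[np.ndarray] = []
    for sigma in sigmas:
        if sigma == 0:
            out.append(amplitude.copy())
            continue
        radius = (kernel_width(sigma) - 1) // 2
        out.append(ndimage.gaussian_filter(amplitude, sigma=sigma, mode="reflect", radius=radius))
    return out


def kernel_width(sigma: float) -> int:
    """Blur kernel support ``d(sigma) = 6*round(sigma) + 1``, round half-up."""
    return 6 * _round_half_up(sigma) + 1


def contrast_series(amplitude: np.ndarray, contrasts: Sequence[float] = (1.0, 0.75, 0.5, 0.25, 0.0)) -> List[np.ndarray]:
    """Mean-preserving contrast ladder: ``mean + c*(A - mean)``, clipped to [0, 1]."""
    amplitude = np.asarray(amplitude, dtype=np.float64)
    mean = amplitude.mean()
    return [np.clip(mean + c * (amplitude - mean), 0.0, 1.0) for c in contrasts]


def multi_height_stack(obj: ObjectField, sim: SimulationSettings = SimulationSettings()) -> HologramStack:
    """Holograms at z, z+dz, ..., z+(n-1)*dz for the multi-height baseline."""
    if sim.plane_count < 2:
        raise ValueError("a multi-height stack needs at least 2 planes")
    holograms = []
    distances = []
    for k in range(sim.plane_count):
        z = sim.distance_um + k * sim.stack_spacing_um
        settings = PropagationSettings(
            wavelength_nm=sim.wavelength_nm, distance_um=z, pitch_um=sim.pitch_um, pad_factor=2
        )
        holo = hologram_intensity(obj, settings)
        holograms.append(Hologram(holo.intensity, settings.with_distance(z)))
        distances.append(z)
    return HologramStack(holograms=holograms, distances_um=distances)
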