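"""Scalar free-space propagation by the angular spectrum method.

Implements the image-formation model of lensless in-line (Gabor) holography:
a thin transparent object ``U_obj = A * exp(j*phi)`` illuminated by a unit
plane wave produces, at a sensor a distance ``z`` away, the intensity
``H = |F^-1{ P(nu; lambda, z) * F(U_obj) }|^2`` where ``P`` is the free-space
optical transfer function.  All propagation here is exact scalar diffraction
(no paraxial approximation); evanescent spatial frequencies, for which
``(lambda*nu)^2 > 1``, are suppressed according to a configurable policy.

Units: wavelengths in nanometres, distances and pixel pitch in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "PropagationSettings",
    "ComplexField",
    "ObjectField",
    "Hologram",
    "transfer_function",
    "propagate",
    "hologram_intensity",
    "backpropagate",
    "field_of_view",
    "coherence_length",
    "coherence_radius",
]


@dataclass(frozen=True)
class PropagationSettings:
    """Geometry and policy for angular-spectrum propagation.

    Parameters
    ----------
    wavelength_nm : float
        Illumination wavelength in nanometres (> 0).
    distance_um : float
        Signed propagation distance in micrometres.  Positive distances
        propagate away from the object (towards the sensor); negative
        distances backpropagate.
    pitch_um : float
        Sensor pixel pitch in micrometres (> 0).
    evanescent_policy : {"zero", "decay"}
        How to treat spatial frequencies beyond the propagating band.
        ``"zero"`` (default) removes them; ``"decay"`` applies the
        exponential attenuation ``exp(-2*pi*z/lambda * sqrt((lambda*nu)^2-1))``.
    pad_factor : int
        1 (circular convolution on the native grid) or 2 (edge-replicated
        padding to suppress wraparound, cropped back after the transform).
    """

    wavelength_nm: float
    distance_um: float
    pitch_um: float
    evanescent_policy: str = "zero"
    pad_factor: int = 1

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError(f"wavelength must be positive, got {self.wavelength_nm}")
        if self.pitch_um <= 0:
            raise ValueError(f"pixel pitch must be positive, got {self.pitch_um}")
        if self.pad_factor not in (1, 2):
            raise ValueError(f"pad_factor must be 1 or 2, got {self.pad_factor}")
        if self.evanescent_policy not in ("zero", "decay"):
            raise ValueError(
                f"evanescent_policy must be 'zero' or 'decay', got {self.evanescent_policy!r}"
            )

    @property
    def wavelength_um(self) -> float:
        return self.wavelength_nm * 1e-3

    def with_distance(self, distance_um: float) -> "PropagationSettings":
        return replace(self, distance_um=distance_um)

    def reversed(self) -> "PropagationSettings":
        return replace(self, distance_um=-self.distance_um)


@dataclass
class ComplexField:
    """A 2-D complex optical field sampled on a uniform grid."""

    values: np.ndarray
    pitch_um: float
    wavelength_nm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("field grid must be 2-D and non-empty")
        if self.pitch_um <= 0 or self.wavelength_nm <= 0:
            raise ValueError("pitch and wavelength must be positive")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        """Wrapped phase mapped to [0, 2*pi)."""
        return np.mod(np.angle(self.values), 2.0 * np.pi)

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    @property
    def power(self) -> float:
        return float(np.sum(self.intensity))


@dataclass
class ObjectField:
    """Thin-object transmission: amplitude A in [0, 1], phase phi in [0, 2*pi)."""

    phase: np.ndarray
    amplitude: np.ndarray
    pitch_um: float

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float64)
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        if self.phase.shape != self.amplitude.shape:
            raise ValueError("phase and amplitude must share a shape")
        if self.phase.ndim != 2:
            raise ValueError("object grids must be 2-D")

    def to_complex(self, wavelength_nm: float) -> ComplexField:
        values = self.amplitude * np.exp(1j * self.phase)
        return ComplexField(values, self.pitch_um, wavelength_nm)


@dataclass
class Hologram:
    """A recorded (or simulated) in-line hologram: nonnegative intensity."""

    intensity: np.ndarray
    settings: PropagationSettings
    background: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 2:
            raise ValueError("hologram intensity must be a 2-D grid")
        if np.any(self.intensity < 0):
            raise ValueError("hologram intensities must be nonnegative")
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=np.float64)
            if self.background.shape != self.intensity.shape:
                raise ValueError("background shape must match the hologram")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.intensity.shape

    def normalized(self) -> "Hologram":
        """Divide by the background (or its mean, or the image mean) so free space ~ 1."""
        if self.background is not None:
            safe = np.where(self.background > 0, self.background, 1.0)
            return Hologram(self.intensity / safe, self.settings)
        mean = float(np.mean(self.intensity))
        if mean <= 0:
            raise ValueError("cannot normalize an all-zero hologram")
        return Hologram(self.intensity / mean, self.settings)


def transfer_function(shape: Tuple[int, int], settings: PropagationSettings) -> np.ndarray:
    """Free-space optical transfer function P(nu; lambda, z) on the DFT lattice.

    ``P = exp(2*pi*j*z/lambda * sqrt(1 - (lambda*nu_x)^2 - (lambda*nu_y)^2))``
    with frequencies ``nu`` on the standard DFT grid (spacing ``1/(N*pitch)``,
    DC at index 0).  Where the radicand is negative the evanescent policy of
    ``settings`` applies.
    """
    ny, nx = shape
    lam = settings.wavelength_um
    z = settings.distance_um
    nu_y = np.fft.fftfreq(ny, d=settings.pitch_um)[:, None]
    nu_x = np.fft.fftfreq(nx, d=settings.pitch_um)[None, :]
    radicand = 1.0 - (lam * nu_x) ** 2 - (lam * nu_y) ** 2
    propagating = radicand >= 0.0
    kz = np.sqrt(np.where(propagating, radicand, 0.0))
    P = np.exp(2j * np.pi * z / lam * kz)
    if settings.evanescent_policy == "zero":
        P = np.where(propagating, P, 0.0 + 0.0j)
    else:  # exponential decay: j*sqrt(|radicand|) in the exponent
        decay = np.exp(-2.0 * np.pi * z / lam * np.sqrt(np.where(propagating, 0.0, -radicand)))
        P = np.where(propagating, P, decay.astype(np.complex128))
    return P


def _pad_edge(values: np.ndarray, factor: int) -> Tuple[np.ndarray, Tuple[slice, slice]]:
    ny, nx = values.shape
    py, px = ny * (factor - 1) // 2, nx * (factor - 1) // 2
    padded = np.pad(values, ((py, py), (px, px)), mode="edge")
    return padded, (slice(py, py + ny), slice(px, px + nx))


def propagate(field: ComplexField, settings: PropagationSettings) -> ComplexField:
    """Angular-spectrum propagation of a complex field by the signed distance.

    Returns ``F^-1{ P * F(field) }`` on the same grid as the input (the
    padded region is cropped away when ``pad_factor > 1``).
    """
    if abs(field.pitch_um - settings.pitch_um) > 1e-12:
        raise ValueError("field and settings disagree on the pixel pitch")
    if abs(field.wavelength_nm - settings.wavelength_nm) > 1e-9:
        raise ValueError("field and settings disagree on the wavelength")
    values = field.values
    crop = None
    if settings.pad_factor > 1:
        values, crop = _pad_edge(values, settings.pad_factor)
    P = transfer_function(values.shape, settings)
    out = np.fft.ifft2(P * np.fft.fft2(values))
    if crop is not None:
        out = out[crop]
    return ComplexField(out, field.pitch_um, field.wavelength_nm)


def hologram_intensity(obj: ObjectField, settings: PropagationSettings) -> Hologram:
    """Simulate the recorded hologram ``H = |P_{lambda,z} (A e^{j phi})|^2``.

    The incident wave is the unit plane wave, so the field leaving the object
    plane is the object transmission itself.
    """
    if not np.all(np.isfinite(obj.amplitude)):
        raise ValueError("object amplitude must be finite")
    u0 = ComplexField(
        obj.amplitude * np.exp(1j * obj.phase), settings.pitch_um, settings.wavelength_nm
    )
    u = propagate(u0, settings)
    return Hologram(u.intensity, settings)


def backpropagate(holo: Hologram, settings: PropagationSettings) -> ComplexField:
    """Propagate the measured intensity image back to the object plane.

    The naive single-shot reconstruction ``U_rec = P_{lambda,-z} H``: the real
    intensity image is treated as a field and propagated by ``-z``.  Because
    the detected phase is lost, the result carries the twin-image artifact —
    no constraint is applied here.
    """
    if np.any(holo.intensity < 0):
        raise ValueError("hologram intensities must be nonnegative")
    f = ComplexField(
        holo.intensity.astype(np.complex128), settings.pitch_um, settings.wavelength_nm
    )
    return propagate(f, settings.with_distance(-settings.distance_um))


# --- closed-form instrument characteristics -------------------------------


def field_of_view(sensor_shape: Tuple[int, int], pitch_um: float) -> Tuple[float, float]:
    """Effective sensor field of view (width, height) in micrometres."""
    ny, nx = sensor_shape
    return nx * pitch_um, ny * pitch_um


def coherence_length(wavelength_nm: float, bandwidth_nm: float) -> float:
    """Temporal coherence length ``lambda^2 / dlambda`` in micrometres (vacuum)."""
    return (wavelength_nm * 1e-3) ** 2 / (bandwidth_nm * 1e-3)


def coherence_radius(wavelength_nm: float, source_distance_cm: float, pinhole_diameter_um: float) -> float:
    """Spatial coherence radius on the sample plane, in micrometres.

    Van Cittert–Zernike estimate ``lambda * z_i / (pi * D)`` for a circular
    pinhole of diameter ``D`` a distance ``z_i`` from the sample.
    """
    lam_um = wavelength_nm * 1e-3
    z_um = source_distance_cm * 1e4
    return lam_um * z_um / (np.pi * pinhole_diameter_um)
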