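"""Quantitative indices for holograms and reconstructions.

* NRMS — normalized root-mean-square deviation of a hologram from its
  reference, a proxy for the scattering power of the recorded pattern.
* PSE — power spectral entropy, the Shannon entropy (bits) of the
  normalized 2-D power spectrum, a proxy for image complexity.
* SSIM — structural similarity, the standard visual-quality index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["nrms", "pse", "ssim", "align_phase", "MetricReport", "PowerSpectrum"]

# SSIM configuration, fixed so reported numbers are comparable across runs:
# uniform 7x7 window, standard stabilizing constants.
SSIM_WINDOW = 7
SSIM_K1 = 0.01
SSIM_K2 = 0.03


@dataclass
class PowerSpectrum:
    """Discrete power spectrum with weights normalized to a distribution."""

    powers: np.ndarray
    weights: np.ndarray

    @classmethod
    def of(cls, image: np.ndarray, exclude_dc: bool = False) -> "PowerSpectrum":
        image = np.asarray(image, dtype=np.float64)
        powers = np.abs(np.fft.fft2(image)) ** 2
        powers = powers.ravel()
        if exclude_dc:
            powers = powers[1:]
        total = powers.sum()
        if total <= 0:
            raise ValueError("image has no spectral power (all zeros)")
        return cls(powers=powers, weights=powers / total)

    def entropy_bits(self) -> float:
        p = self.weights[self.weights > 0]
        return float(-np.sum(p * np.log2(p)))


def nrms(holo: np.ndarray, ref: np.ndarray) -> float:
    """``RMS(holo - ref) / RMS(ref)``.

    Scale-covariant: multiplying both images by c > 0 leaves it unchanged.
    """
    holo = np.asarray(holo, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if holo.shape != ref.shape:
        raise ValueError(f"shape mismatch: {holo.shape} vs {ref.shape}")
    ref_rms = np.sqrt(np.mean(ref**2))
    if ref_rms == 0:
        raise ValueError("reference has zero RMS; NRMS undefined")
    return float(np.sqrt(np.mean((holo - ref) ** 2)) / ref_rms)


def pse(image: np.ndarray, exclude_dc: bool = False) -> float:
    """Power spectral entropy of a 2-D image, in bits.

    The 2-D DFT power spectrum ``|F(image)|^2`` is normalized to a
    probability distribution p_i over all N^2 components (DC included by
    default) and its Shannon entropy ``-sum p_i log2 p_i`` is returned,
    with the convention ``0*log(0) = 0``.  Invariant to intensity scaling
    and to spatial translation.
    """
    return PowerSpectrum.of(image, exclude_dc=exclude_dc).entropy_bits()


def ssim(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Structural similarity with a uniform 7x7 window; symmetric in (a, b)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(
        structural_similarity(
            a,
            b,
            win_size=SSIM_WINDOW,
            gaussian_weights=False,
            K1=SSIM_K1,
            K2=SSIM_K2,
            data_range=data_range,
        )
    )


def align_phase(phase: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Gauge-align a reconstructed phase map to a reference.

    An intensity measurement fixes the object phase only up to an additive
    constant (a global phase multiplies the field by a unit complex number
    and leaves every hologram unchanged), and wrapped maps additionally
    suffer 0/2*pi splitting of a flat background.  This removes both
    nuisances before comparison: the circular-mean offset
    ``theta = angle(mean(exp(j*(reference - phase))))`` is added, and the
    result is expressed as ``reference + wrapped deviation`` so it is
    continuous wherever the reconstruction tracks the reference.  Apply it
    identically to every method being compared.
    """
    phase = np.asarray(phase, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if phase.shape != reference.shape:
        raise ValueError(f"shape mismatch: {phase.shape} vs {reference.shape}")
    theta = np.angle(np.mean(np.exp(1j * (reference - phase))))
    deviation = np.angle(np.exp(1j * (phase + theta - reference)))
    return reference + deviation


@dataclass
class MetricReport:
    """Bundle of quality indices for one reconstruction vs its ground truth."""

    nrms: Optional[float] = None
    pse: Optional[float] = None
    ssim_amplitude: Optional[float] = None
    ssim_phase: Optional[float] = None
    ssim_window: int = SSIM_WINDOW
    ssim_k1: float = SSIM_K1
    ssim_k2: float = SSIM_K2
    ssim_data_range: float = 1.0

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}
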