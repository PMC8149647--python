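"""Reference reconstructions: plain backpropagation and multi-height phase recovery.

Backpropagation propagates the measured intensity back to the object plane in
one step and exhibits the twin-image artifact in full.  Multi-height phase
recovery (MHPR) is the classical alternating-projection scheme over holograms
recorded at several sample-to-sensor distances: the field is propagated from
plane to plane, and at each plane its modulus is replaced by the measured
sqrt-intensity while the computed phase is retained.  With enough planes the
phase converges and the twin image is strongly suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .wave_optics import (
    ComplexField,
    Hologram,
    ObjectField,
    PropagationSettings,
    backpropagate,
    propagate,
)

__all__ = ["HologramStack", "mhpr", "backpropagation_baseline"]


@dataclass
class HologramStack:
    """Ordered holograms with strictly increasing object-to-sensor distances."""

    holograms: List[Hologram]
    distances_um: List[float]

    def __post_init__(self) -> None:
        if len(self.holograms) != len(self.distances_um):
            raise ValueError("one distance per hologram is required")
        if len(self.holograms) >= 2:
            d = np.asarray(self.distances_um, dtype=np.float64)
            if np.any(np.diff(d) <= 0):
                raise ValueError("distances must be strictly increasing")
        shapes = {h.shape for h in self.holograms}
        pitches = {h.settings.pitch_um for h in self.holograms}
        if len(shapes) > 1 or len(pitches) > 1:
            raise ValueError("all holograms must share shape and pixel pitch")

    def __len__(self) -> int:
        return len(self.holograms)


def mhpr(
    stack: HologramStack,
    rounds: int = 20,
    seed: int = 0,
    residual_history: Optional[List[float]] = None,
) -> ComplexField:
    """Multi-height phase recovery by alternating projections.

    Starts at the first measurement plane with amplitude ``sqrt(H_1)`` and
    zero phase; each round sweeps forward through the planes and wraps back
    to the first, replacing the field modulus with the measured one at every
    plane while keeping the evolved phase.  After the final round the field
    is backpropagated from the first plane to the object plane.

    ``seed`` is accepted for interface uniformity; the default zero-phase
    initialization is deterministic.  If ``residual_history`` is a list, the
    mean absolute intensity mismatch at the first plane (measured on return
    to it, before projecting) is appended once per round — the alternating
    projections' error-reduction trace.
    """
    if len(stack) < 2:
        raise ValueError(
            "MHPR needs >= 2 planes; for a single hologram use backpropagate()"
        )
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    base = stack.holograms[0].settings
    amplitudes = [np.sqrt(h.intensity) for h in stack.holograms]
    distances = stack.distances_um
    n = len(stack)

    field = ComplexField(
        amplitudes[0].astype(np.complex128), base.pitch_um, base.wavelength_nm
    )
    for _ in range(rounds):
        for k in range(1, n):
            field = propagate(field, base.with_distance(distances[k] - distances[k - 1]))
            field = ComplexField(
                amplitudes[k] * np.exp(1j * np.angle(field.values)),
                base.pitch_um,
                base.wavelength_nm,
            )
        # wrap back to the first plane and project there
        field = propagate(field, base.with_distance(distances[0] - distances[-1]))
        if residual_history is not None:
            residual_history.append(
                float(np.mean(np.abs(np.abs(field.values) ** 2 - stack.holograms[0].intensity)))
            )
        field = ComplexField(
            amplitudes[0] * np.exp(1j * np.angle(field.values)),
            base.pitch_um,
            base.wavelength_nm,
        )
    return propagate(field, base.with_distance(-distances[0]))


def backpropagation_baseline(holo: Hologram) -> ObjectField:
    """Single-shot backpropagation, split into modulus and wrapped phase.

    The returned phase is mapped to [0, 2*pi).  Twin-image noise is left in
    place — this is the uncorrected reference every phase-retrieval method
    is compared against.
    """
    rec = backpropagate(holo, holo.settings)
    return ObjectField(phase=rec.phase, amplitude=rec.amplitude, pitch_um=holo.settings.pitch_um)
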