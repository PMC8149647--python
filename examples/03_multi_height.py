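"""Multi-height phase recovery over a six-plane hologram stack.

Simulates holograms of a pure-amplitude object at 300, 350, ..., 550 um,
runs 20 rounds of alternating projections, and shows the per-round residual
shrinking alongside the final amplitude quality vs single-shot
backpropagation of the first plane.
"""

import numpy as np

from dcod import (
    Hologram,
    HologramStack,
    ObjectField,
    PropagationSettings,
    SimulationSettings,
    backpropagation_baseline,
    make_phantom,
    mhpr,
    multi_height_stack,
    ssim,
)

blobs = make_phantom("blobs", size=64, seed=3)
truth = ObjectField(np.zeros_like(blobs.phase), blobs.amplitude, blobs.pitch_um)
padded = multi_height_stack(truth, SimulationSettings())
stack = HologramStack(
    [
        Hologram(h.intensity, PropagationSettings(532.2, z, 1.12))
        for h, z in zip(padded.holograms, padded.distances_um)
    ],
    padded.distances_um,
)

residuals: list = []
field = mhpr(stack, rounds=20, residual_history=residuals)
bp = backpropagation_baseline(stack.holograms[0])

print("plane distances (um):", stack.distances_um)
print("round  1 residual: %.5f" % residuals[0])
print("round 20 residual: %.5f  (mean |I - H| at the first plane)" % residuals[-1])
print(f"MHPR amplitude SSIM:     {ssim(np.clip(field.amplitude, 0, 1), truth.amplitude):.3f}")
print(f"backprop amplitude SSIM: {ssim(np.clip(bp.amplitude, 0, 1), truth.amplitude):.3f}")
print()
print("Each extra plane constrains the lost phase; alternating projections")
print("drive the intensity mismatch down monotonically and suppress the twin.")
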