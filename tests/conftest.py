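"""Shared fixtures.

The iterative reconstructions are expensive (minutes each), so every scaled
run is computed once per session and shared by all tests that assert on it.
Study conditions: 64x64 blob phantom at the reference optics (532.2 nm,
z = 300 um, 1.12 um pitch), reduced decoder (8x8 input, 3 layers, width 64),
2000 main iterations (+500 refinement for the regularized run).
"""

from __future__ import annotations

import numpy as np
import pytest

import dcod
from dcod.baselines import backpropagation_baseline, mhpr
from dcod.decoder import DecoderConfig
from dcod.reconstruct import OptimizerConfig, PerturbationSchedule, reconstruct, reconstruct_phase_only
from dcod.synth import SimulationSettings, make_phantom, multi_height_stack, simulate_hologram
from dcod.wave_optics import Hologram, ObjectField, PropagationSettings

SEED = 3
SIZE = 64
TWO_PI = 2.0 * np.pi


@pytest.fixture(scope="session")
def scaled_net() -> DecoderConfig:
    return DecoderConfig.scaled()  # 8x8 input, depth 3, width 64 -> 64x64 output


@pytest.fixture(scope="session")
def blobs_object() -> ObjectField:
    return make_phantom("blobs", SIZE, seed=SEED)


@pytest.fixture(scope="session")
def blobs_hologram(blobs_object) -> Hologram:
    return simulate_hologram(blobs_object, SimulationSettings())


@pytest.fixture(scope="session")
def backprop_object(blobs_hologram) -> ObjectField:
    return backpropagation_baseline(blobs_hologram)


@pytest.fixture(scope="session")
def dcod_result(blobs_hologram, scaled_net):
    """Full regularized reconstruction: 2000 AdamW iterations + 500 refinement."""
    return reconstruct(
        blobs_hologram,
        net_cfg=scaled_net,
        opt_cfg=OptimizerConfig(iterations=2000, refine_iterations=500),
        schedule=PerturbationSchedule(),
        seed=0,
    )


@pytest.fixture(scope="session")
def ablation_result(blobs_hologram, scaled_net):
    """Unregularized control: same budget, no weight decay, no perturbation."""
    return reconstruct(
        blobs_hologram,
        net_cfg=scaled_net,
        opt_cfg=OptimizerConfig(weight_decay=0.0, iterations=2500, refine_iterations=0),
        schedule=PerturbationSchedule.disabled(),
        seed=0,
    )


@pytest.fixture(scope="session")
def pure_phase_object(blobs_object) -> ObjectField:
    return ObjectField(
        phase=blobs_object.phase,
        amplitude=np.ones_like(blobs_object.amplitude),
        pitch_um=blobs_object.pitch_um,
    )


@pytest.fixture(scope="session")
def pure_phase_hologram(pure_phase_object) -> Hologram:
    return simulate_hologram(pure_phase_object, SimulationSettings())


@pytest.fixture(scope="session")
def phase_only_pure_result(pure_phase_hologram, scaled_net):
    return reconstruct_phase_only(
        pure_phase_hologram,
        net_cfg=scaled_net,
        opt_cfg=OptimizerConfig(weight_decay=0.0, iterations=2000, refine_iterations=0),
        seed=0,
        background=1.0,
    )


@pytest.fixture(scope="session")
def phase_only_contrast_result(blobs_hologram, scaled_net):
    """Phase-only baseline misapplied to an object with real absorption."""
    return reconstruct_phase_only(
        blobs_hologram,
        net_cfg=scaled_net,
        opt_cfg=OptimizerConfig(weight_decay=0.0, iterations=2000, refine_iterations=0),
        seed=0,
        background=1.0,
    )


@pytest.fixture(scope="session")
def amplitude_stack(blobs_object):
    """6-plane noise-free stack of a pure-amplitude object, unpadded settings."""
    pure_amp = ObjectField(
        phase=np.zeros_like(blobs_object.phase),
        amplitude=blobs_object.amplitude,
        pitch_um=blobs_object.pitch_um,
    )
    stack = multi_height_stack(pure_amp, SimulationSettings())
    holograms = [
        dcod.Hologram(
            h.intensity,
            PropagationSettings(
                wavelength_nm=h.settings.wavelength_nm,
                distance_um=z,
                pitch_um=h.settings.pitch_um,
                pad_factor=1,
            ),
        )
        for h, z in zip(stack.holograms, stack.distances_um)
    ]
    return pure_amp, dcod.HologramStack(holograms, stack.distances_um)


@pytest.fixture(scope="session")
def mhpr_run(amplitude_stack):
    _, stack = amplitude_stack
    residuals: list = []
    field = mhpr(stack, rounds=20, residual_history=residuals)
    return field, residuals
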