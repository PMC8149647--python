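"""Deep decoder: initialization, normalization, forward pass, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from dcod import decoder as dec
from dcod.decoder import (
    CHANNEL_NORM_EPS,
    DecoderConfig,
    channel_normalize,
    count_parameters,
    fit_to_image,
    forward,
    init_state,
)

TOY = DecoderConfig(depth=2, channels=(8, 8, 8), input_size=4)


class TestInitState:
    def test_default_base_tensor_shape(self):
        state = init_state(DecoderConfig(), seed=0)
        assert state.base_input.shape == (256, 16, 16)

    def test_same_seed_reproduces_state_bitwise(self):
        a, b = init_state(TOY, seed=42), init_state(TOY, seed=42)
        np.testing.assert_array_equal(a.base_input, b.base_input)
        for wa, wb in zip(a.trainables(), b.trainables()):
            np.testing.assert_array_equal(wa, wb)

    def test_base_tensor_statistics(self):
        """65,536 draws pin mean ~0 and std ~0.1 by the law of large numbers."""
        state = init_state(DecoderConfig(), seed=1)
        assert abs(state.base_input.mean()) < 0.01
        assert abs(state.base_input.std() - 0.1) < 0.01

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError):
            DecoderConfig(depth=2, channels=(8, 8), input_size=4)


class TestChannelNormalize:
    def test_standardizes_nonconstant_channel(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(2.0, 3.0, size=(1, 16, 16))
        out = channel_normalize(Z, np.ones(1), np.zeros(1))
        assert out.mean() == pytest.approx(0.0, abs=1e-6)
        assert out.std() == pytest.approx(1.0, abs=1e-3)  # std/(std+eps) offset

    def test_constant_channel_collapses_to_beta(self):
        Z = np.full((1, 8, 8), 5.0)
        out = channel_normalize(Z, np.ones(1), np.array([0.3]))
        np.testing.assert_allclose(out, 0.3, atol=1e-12)

    def test_matches_two_loop_evaluation(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(3, 8, 8))
        gamma, beta = rng.normal(size=3), rng.normal(size=3)
        out = channel_normalize(Z, gamma, beta)
        for j in range(3):
            m, s = Z[j].mean(), Z[j].std()
            for iy in range(8):
                for ix in range(8):
                    expect = (Z[j, iy, ix] - m) / (s + CHANNEL_NORM_EPS) * gamma[j] + beta[j]
                    assert out[j, iy, ix] == pytest.approx(expect, abs=1e-10)


class TestForward:
    def test_default_config_output_geometry(self):
        cfg = DecoderConfig()
        assert cfg.output_size == 512
        obj = forward(init_state(cfg.scaled(input_size=4, depth=2, width=8), 0))
        assert obj.phase.shape == obj.amplitude.shape

    def test_zero_weights_give_midrange_output(self):
        state = init_state(TOY, seed=0)
        for w in state.weights:
            w[:] = 0.0
        state.out_weight[:] = 0.0
        obj = forward(state)
        np.testing.assert_allclose(obj.phase, np.pi, atol=1e-12)
        np.testing.assert_allclose(obj.amplitude, 0.5, atol=1e-12)

    def test_matches_hand_rolled_composition(self):
        """Independent re-implementation: explicit upsample/matmul/relu/norm."""
        state = init_state(TOY, seed=7)
        obj = forward(state)

        def up(x):  # half-pixel bilinear, edge-clamped, written longhand
            k, n, _ = x.shape
            out = np.zeros((k, 2 * n, 2 * n))
            for c in range(k):
                rows = np.zeros((2 * n, n))
                for m in range(n):
                    rows[2 * m] = 0.25 * x[c, max(m - 1, 0)] + 0.75 * x[c, m]
                    rows[2 * m + 1] = 0.75 * x[c, m] + 0.25 * x[c, min(m + 1, n - 1)]
                for m in range(n):
                    out[c, :, 2 * m] = 0.25 * rows[:, max(m - 1, 0)] + 0.75 * rows[:, m]
                    out[c, :, 2 * m + 1] = 0.75 * rows[:, m] + 0.25 * rows[:, min(m + 1, n - 1)]
            return out

        x = state.base_input
        for i in range(TOY.depth):
            u = up(x)
            z = np.maximum(np.einsum("ixy,io->oxy", u, state.weights[i]), 0.0)
            x = channel_normalize(z, state.gammas[i], state.betas[i])
        logits = np.einsum("ixy,io->oxy", x, state.out_weight)
        sig = 1.0 / (1.0 + np.exp(-logits))
        np.testing.assert_allclose(obj.phase, 2 * np.pi * sig[0], atol=1e-8)
        np.testing.assert_allclose(obj.amplitude, sig[1], atol=1e-8)

    def test_forward_is_pure(self):
        state = init_state(TOY, seed=3)
        a = forward(state)
        b = forward(state)
        np.testing.assert_array_equal(a.phase, b.phase)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @hsettings(max_examples=15, deadline=None, derandomize=True)
    def test_output_bounds_hold_for_any_weights(self, seed):
        state = init_state(TOY, seed=0)
        rng = np.random.default_rng(seed)
        for arr in state.trainables():
            arr[:] = rng.normal(0.0, 10.0, size=arr.shape)  # wild weights
        obj = forward(state)
        assert obj.phase.min() >= 0.0 and obj.phase.max() <= 2 * np.pi
        assert obj.amplitude.min() >= 0.0 and obj.amplitude.max() <= 1.0


class TestCountParameters:
    def test_default_network_is_under_parameterized(self):
        cfg = DecoderConfig()
        assert count_parameters(cfg) == 330_752
        assert count_parameters(cfg) < 2 * 512 * 512

    def test_hand_counted_toy_config(self):
        cfg = DecoderConfig(depth=1, channels=(4, 4), input_size=4)
        # 4*4 conv + (4 gammas + 4 betas) + 4*2 output = 32
        assert count_parameters(cfg) == 32

    def test_count_independent_of_spatial_size(self):
        a = DecoderConfig(depth=2, channels=(8, 8, 8), input_size=4)
        b = DecoderConfig(depth=2, channels=(8, 8, 8), input_size=16)
        assert count_parameters(a) == count_parameters(b)


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """Analytic gradients through upsample/conv/relu/norm/sigmoid chain."""
        cfg = DecoderConfig(depth=2, channels=(5, 6, 7), input_size=4)
        state = init_state(cfg, seed=1)
        rng = np.random.default_rng(0)
        n = cfg.output_size
        t_phase = rng.uniform(0, 2 * np.pi, (n, n))
        t_amp = rng.uniform(0, 1, (n, n))

        def loss_of(s):
            obj = forward(s)
            return float(np.mean((obj.phase - t_phase) ** 2) + np.mean((obj.amplitude - t_amp) ** 2))

        phase, amp, cache = dec.forward_with_cache(state)
        grads = dec.backward(
            state,
            cache,
            g_phase=2 * (phase - t_phase) / t_phase.size,
            g_amplitude=2 * (amp - t_amp) / t_amp.size,
        )
        eps = 1e-6
        for arr, garr in zip(state.trainables(), grads.trainables()):
            flat_idx = rng.choice(arr.size, size=min(4, arr.size), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = loss_of(state)
                arr[idx] = orig - eps
                lm = loss_of(state)
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert garr[idx] == pytest.approx(fd, rel=1e-4, abs=1e-9)

    def test_upsample_adjoint_identity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(3, 6, 6))
        y = rng.normal(size=(3, 12, 12))
        lhs = np.sum(dec._upsample2(x) * y)
        rhs = np.sum(x * dec._upsample2_adjoint(y))
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestCheckpointing:
    def test_state_round_trips_through_npz(self, tmp_path):
        state = init_state(TOY, seed=5)
        path = tmp_path / "state.npz"
        dec.save_state(path, state)
        back = dec.load_state(path)
        assert back.config == TOY
        np.testing.assert_array_equal(back.base_input, state.base_input)
        for a, b in zip(back.trainables(), state.trainables()):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(forward(back).phase, forward(state).phase)


class TestFittingCapacity:
    def test_decoder_alone_fits_a_smooth_target(self):
        """Deep-image-prior premise: MSE < 1e-3 on a 64x64 target in 2000 steps."""
        from dcod.synth import make_phantom

        target = make_phantom("blobs", 64, seed=7).amplitude
        _, losses = fit_to_image(target, DecoderConfig.scaled(), iterations=2000, seed=0)
        assert losses[-1] < 1e-3
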