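"""Window geometry, attention oracles, block structure and complexity forms."""

import numpy as np
import pytest

from leafswin.autodiff import Tensor
from leafswin.nn import Linear
from leafswin.swin import (ModelConfig, PatchMerging, SwinBlock, SwinChannel,
                           WindowAttention, complexity_estimate, patch_partition,
                           relative_position_index, shift_attention_mask,
                           window_partition, window_reverse)


def dense_window_attention(x, wq, bq, wproj, bproj, num_heads, scale,
                           bias_table=None, rel_index=None, mask=None):
    """Brute-force multi-head attention for one window (oracle).

    ``x``: (N, C); weights taken straight from the module under test but the
    computation is plain softmax attention written independently.
    """
    n, c = x.shape
    d = c // num_heads
    qkv = x @ wq + bq
    q, k, v = qkv[:, :c], x @ wq[:, c:2 * c] + bq[c:2 * c], qkv[:, 2 * c:]
    out = np.zeros((n, c))
    for h in range(num_heads):
        qh = q[:, h * d:(h + 1) * d]
        kh = k[:, h * d:(h + 1) * d]
        vh = v[:, h * d:(h + 1) * d]
        logits = qh @ kh.T * scale
        if bias_table is not None:
            logits = logits + bias_table[rel_index, h].reshape(n, n)
        if mask is not None:
            logits = logits + mask
        logits = logits - logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        out[:, h * d:(h + 1) * d] = probs @ vh
    return out @ wproj + bproj


class TestPatchPartition:
    @pytest.mark.parametrize("size,expected_grid", [(224, 56), (8, 2)])
    def test_grid_and_token_dim(self, size, expected_grid, rng):
        img = rng.random((1, size, size, 3)).astype(np.float32)
        tokens = patch_partition(Tensor(img), 4)
        assert tokens.shape == (1, expected_grid, expected_grid, 48)

    def test_constant_image_gives_identical_tokens(self):
        img = np.full((1, 8, 8, 3), 0.4)
        tokens = patch_partition(Tensor(img), 4).data.reshape(-1, 48)
        np.testing.assert_allclose(tokens, np.broadcast_to(tokens[0], tokens.shape))

    def test_non_divisible_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            patch_partition(Tensor(rng.random((1, 10, 10, 3))), 4)

    def test_tokens_are_patch_pixels(self, rng):
        img = rng.random((1, 8, 8, 3))
        tokens = patch_partition(Tensor(img), 4).data
        np.testing.assert_allclose(tokens[0, 0, 1], img[0, 0:4, 4:8].reshape(-1))


class TestLinearEmbed:
    def test_shape_projection(self, rng):
        lin = Linear(48, 96, rng=rng)
        out = lin(Tensor(rng.random((5, 48)).astype(np.float32)))
        assert out.shape == (5, 96)

    def test_zero_input_zero_bias_is_zero(self, rng):
        lin = Linear(48, 96, rng=rng)
        lin.bias.data[:] = 0.0
        np.testing.assert_allclose(lin(Tensor(np.zeros((3, 48)))).data, 0.0)

    def test_identity_padded_projection(self, rng):
        lin = Linear(48, 96, rng=rng)
        lin.weight.data[:] = 0.0
        lin.weight.data[:48, :48] = np.eye(48)
        lin.bias.data[:] = 0.0
        x = rng.random((2, 48)).astype(np.float32)
        out = lin(Tensor(x)).data
        np.testing.assert_allclose(out[:, :48], x, atol=1e-6)
        np.testing.assert_allclose(out[:, 48:], 0.0)


class TestWindowGeometry:
    def test_14x14_m7_gives_four_windows(self, rng):
        grid = Tensor(rng.random((1, 14, 14, 8)))
        assert window_partition(grid, 7).shape == (4, 49, 8)

    @pytest.mark.parametrize("shift", [0, 3])
    def test_partition_reverse_roundtrip(self, shift, rng):
        g = rng.random((2, 14, 14, 5))
        w = window_partition(Tensor(g), 7, shift=shift)
        back = window_reverse(w, 7, 14, 14, shift=shift)
        np.testing.assert_array_equal(back.data, g)

    def test_shifted_partition_matches_index_oracle(self, rng):
        g = rng.random((1, 14, 14, 1))
        shift = 3
        w = window_partition(Tensor(g), 7, shift=shift).data[..., 0]
        rolled = np.roll(g[0, :, :, 0], (-shift, -shift), axis=(0, 1))
        for wi in range(2):
            for wj in range(2):
                block = rolled[wi * 7:(wi + 1) * 7, wj * 7:(wj + 1) * 7].reshape(-1)
                np.testing.assert_array_equal(w[wi * 2 + wj], block)

    def test_non_divisible_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            window_partition(Tensor(rng.random((1, 10, 10, 4))), 7)


class TestWindowAttention:
    def test_matches_dense_oracle(self, rng):
        attn = WindowAttention(dim=12, num_heads=3, window_size=7, rng=rng)
        x = rng.normal(size=(4, 49, 12)).astype(np.float32)
        out = attn(Tensor(x)).data
        rel = relative_position_index(7).reshape(-1)
        for w in range(4):
            expected = dense_window_attention(
                x[w].astype(np.float64), attn.qkv.weight.data, attn.qkv.bias.data,
                attn.proj.weight.data, attn.proj.bias.data, 3, attn.scale,
                bias_table=attn.bias_table.data, rel_index=rel)
            np.testing.assert_allclose(out[w], expected, atol=1e-5)

    def test_single_token_window_attends_to_itself(self, rng):
        attn = WindowAttention(dim=4, num_heads=2, window_size=1, rng=rng)
        x = rng.normal(size=(3, 1, 4)).astype(np.float32)
        _, probs = attn(Tensor(x), return_attn=True)
        np.testing.assert_array_equal(probs, 1.0)

    def test_identical_tokens_split_attention_evenly(self, rng):
        attn = WindowAttention(dim=4, num_heads=1, window_size=1, rng=rng,
                               rel_pos_bias=False)
        # hand-build a 2-token window by bypassing geometry: window_size only
        # sizes the bias table, which is disabled here
        x = np.tile(rng.normal(size=(1, 1, 4)), (1, 2, 1)).astype(np.float32)
        _, probs = attn(Tensor(x), return_attn=True)
        np.testing.assert_allclose(probs, 0.5, atol=1e-6)

    def test_rows_sum_to_one(self, rng):
        attn = WindowAttention(dim=8, num_heads=2, window_size=2, rng=rng)
        x = rng.normal(size=(2, 4, 8)).astype(np.float32)
        _, probs = attn(Tensor(x), return_attn=True)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_bad_head_count_rejected(self, rng):
        with pytest.raises(ValueError, match="head"):
            WindowAttention(dim=10, num_heads=3, window_size=2, rng=rng)


class TestShiftedAttention:
    def test_zero_shift_mask_is_all_zero(self):
        mask = shift_attention_mask(14, 14, 7, 0)
        np.testing.assert_array_equal(mask, 0.0)

    def test_cross_provenance_mass_exactly_zero(self, rng):
        """On a 14x14 grid, shifted attention between tokens from disjoint
        pre-shift windows is exactly 0 after normalization."""
        shift = 3
        mask = shift_attention_mask(14, 14, 7, shift)
        attn = WindowAttention(dim=8, num_heads=2, window_size=7, rng=rng)
        g = rng.normal(size=(1, 14, 14, 8)).astype(np.float32)
        windows = window_partition(Tensor(g), 7, shift=shift)
        _, probs = attn(windows, mask=mask, return_attn=True)
        blocked = np.isinf(mask)            # (nW, 49, 49)
        for w in range(4):
            assert np.all(probs[w][:, blocked[w]] == 0.0)
        # every row still normalizes
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)
        # and some windows do have blocked pairs
        assert blocked.any()

    def test_mask_symmetric(self):
        mask = shift_attention_mask(14, 14, 7, 3)
        np.testing.assert_array_equal(mask, np.swapaxes(mask, 1, 2))

    def test_uniform_grid_gives_spatially_constant_output(self, rng):
        block = SwinBlock(dim=8, grid_size=14, num_heads=2, window_size=7,
                          shift=3, mlp_ratio=2.0, rng=rng)
        g = np.tile(rng.normal(size=(1, 1, 1, 8)), (1, 14, 14, 1)).astype(np.float32)
        out = block(Tensor(g)).data
        np.testing.assert_allclose(out, np.broadcast_to(out[:, :1, :1, :], out.shape), atol=1e-5)


class TestSwinBlock:
    @pytest.mark.parametrize("shift", [0, 3])
    def test_zeroed_output_projections_make_identity(self, shift, rng):
        block = SwinBlock(dim=8, grid_size=14, num_heads=2, window_size=7,
                          shift=shift, mlp_ratio=2.0, rng=rng)
        block.attn.proj.weight.data[:] = 0.0
        block.attn.proj.bias.data[:] = 0.0
        block.mlp.fc2.weight.data[:] = 0.0
        block.mlp.fc2.bias.data[:] = 0.0
        x = rng.normal(size=(1, 14, 14, 8)).astype(np.float32)
        np.testing.assert_allclose(block(Tensor(x)).data, x, atol=1e-7)

    def test_matches_stepwise_residual_recurrence(self, rng):
        """Block output equals the literal pre-norm residual composition."""
        block = SwinBlock(dim=8, grid_size=14, num_heads=2, window_size=7,
                          shift=0, mlp_ratio=2.0, rng=rng)
        x = rng.normal(size=(1, 14, 14, 8)).astype(np.float32)
        t = Tensor(x)
        mid = t + block._attend(block.norm1(t))
        expected = mid + block.mlp(block.norm2(mid))
        np.testing.assert_allclose(block(Tensor(x)).data, expected.data, atol=1e-6)

    def test_shape_preserved(self, rng):
        block = SwinBlock(dim=8, grid_size=14, num_heads=2, window_size=7,
                          shift=3, mlp_ratio=2.0, rng=rng)
        x = rng.normal(size=(2, 14, 14, 8)).astype(np.float32)
        assert block(Tensor(x)).shape == (2, 14, 14, 8)

    def test_full_grid_window_disables_shift(self, rng):
        block = SwinBlock(dim=8, grid_size=7, num_heads=2, window_size=7,
                          shift=3, mlp_ratio=2.0, rng=rng)
        assert block.shift == 0


class TestPatchMerging:
    def test_halves_space_doubles_channels(self, rng):
        merge = PatchMerging(dim=6, rng=rng)
        out = merge(Tensor(rng.normal(size=(1, 4, 4, 6)).astype(np.float32)))
        assert out.shape == (1, 2, 2, 12)

    def test_smallest_instance(self, rng):
        merge = PatchMerging(dim=3, rng=rng)
        out = merge(Tensor(rng.normal(size=(1, 2, 2, 3)).astype(np.float32)))
        assert out.shape == (1, 1, 1, 6)

    def test_constant_grid_merges_identically(self, rng):
        merge = PatchMerging(dim=4, rng=rng)
        g = np.tile(rng.normal(size=(1, 1, 1, 4)), (1, 4, 4, 1)).astype(np.float32)
        out = merge(Tensor(g)).data.reshape(-1, 8)
        np.testing.assert_allclose(out, np.broadcast_to(out[0], out.shape), atol=1e-6)

    def test_odd_grid_rejected(self, rng):
        merge = PatchMerging(dim=4, rng=rng)
        with pytest.raises(ValueError, match="even"):
            merge(Tensor(np.zeros((1, 3, 4, 4), dtype=np.float32)))


class TestChannelForward:
    def test_stage_resolutions_and_pooled_width(self, rng):
        cfg = ModelConfig(image_size=56, embed_dim=16, depths=(2, 2), num_heads=(2, 4),
                          num_classes=2)
        channel = SwinChannel(cfg, np.random.default_rng(0))
        img = Tensor(rng.random((1, 56, 56, 3)).astype(np.float32))
        grids = channel.stage_grids(img)
        assert [g.shape for g in grids] == [(1, 14, 14, 16), (1, 7, 7, 32)]
        pooled = channel(img)
        assert pooled.shape == (1, cfg.feature_dim) == (1, 32)

    def test_deterministic_in_eval_mode(self, rng):
        cfg = ModelConfig(image_size=56, embed_dim=16, depths=(2,), num_heads=(2,),
                          num_classes=2)
        channel = SwinChannel(cfg, np.random.default_rng(0)).eval()
        img = rng.random((1, 56, 56, 3)).astype(np.float32)
        a = channel(Tensor(img)).data
        b = channel(Tensor(img)).data
        np.testing.assert_array_equal(a, b)

    def test_geometry_validation_before_compute(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(image_size=100)
        with pytest.raises(ValueError, match="window"):
            ModelConfig(image_size=96, window_size=7, depths=(2,), num_heads=(2,))


class TestComplexity:
    def test_hand_evaluated_values(self):
        rep = complexity_estimate(2, 2, 1, 1)
        assert rep.omega_msa == 48            # 4*4*1 + 2*16*1
        assert rep.omega_wmsa == 24           # 4*4*1 + 2*1*4*1
        assert complexity_estimate(8, 8, 2, 2).omega_wmsa == 2048

    def test_growth_orders(self):
        # doubling hw doubles the windowed cost but quadruples the dominant
        # global-attention term
        small = complexity_estimate(8, 8, 4, 2)
        big = complexity_estimate(16, 8, 4, 2)
        assert big.omega_wmsa == 2 * small.omega_wmsa
        quad_small = small.omega_msa - 4 * 64 * 16
        quad_big = big.omega_msa - 4 * 128 * 16
        assert quad_big == 4 * quad_small

    def test_single_window_limit_recovers_global_cost(self):
        # with M^2 = hw the window covers the whole image: second terms agree
        rep = complexity_estimate(4, 4, 3, 4)
        assert rep.omega_msa == rep.omega_wmsa

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            complexity_estimate(0, 2, 1, 1)
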