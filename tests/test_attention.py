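"""Attention mathematics against explicit-loop oracles.

The reference computations here are deliberately naive (double loops,
per-pair softmax) so they stay independent of the vectorized
implementation they validate.
"""

import math

import numpy as np
import pytest

from edtnet import autodiff as ad
from edtnet.attention import (AttentionConfig, AttentionProjections,
                              CrossAttention, ESGABlock, ESLABlock,
                              PositionalEncoding, SkipAttentionFuse, TokenGrid,
                              add_positional_encoding, attention_weights,
                              biased_attention, conv_patch_embed,
                              relative_position_index, relative_spatial_bias,
                              SpatialBiasTable, window_partition, window_reverse)
from edtnet.autodiff import Tensor
from edtnet.losses import hybrid_loss


def naive_attention(tokens, wq, wk, wv, wout, heads, head_dim, bias=None):
    """Explicit-loop multi-head scaled-dot-product attention oracle."""
    n, _ = tokens.shape
    q = tokens @ wq
    k = tokens @ wk
    v = tokens @ wv
    out_heads = []
    for h in range(heads):
        sl = slice(h * head_dim, (h + 1) * head_dim)
        qh, kh, vh = q[:, sl], k[:, sl], v[:, sl]
        res = np.zeros((n, head_dim))
        for i in range(n):
            scores = np.array([qh[i] @ kh[j] / math.sqrt(head_dim)
                               for j in range(n)])
            if bias is not None:
                scores = scores + bias[h, i]
            e = np.exp(scores - scores.max())
            a = e / e.sum()
            res[i] = sum(a[j] * vh[j] for j in range(n))
        out_heads.append(res)
    return np.concatenate(out_heads, axis=1) @ wout


def make_proj(dim, cfg, rng, kv_dim=None, w_prime=False):
    return AttentionProjections(dim, cfg, rng, kv_dim=kv_dim, w_prime=w_prime)


class TestPatchEmbedding:
    def test_grid_shape_arithmetic(self, rng):
        img = rng.uniform(size=(1, 3, 256, 256))
        w = rng.normal(size=(8, 3, 4, 4))
        grid = conv_patch_embed(Tensor(img), Tensor(w), None, stride=4)
        assert (grid.h, grid.w, grid.d) == (64, 64, 8)

    def test_identity_kernel_on_constant_image(self):
        img = np.full((1, 1, 8, 8), 0.7)
        w = np.ones((1, 1, 1, 1))
        grid = conv_patch_embed(Tensor(img), Tensor(w), None, stride=1)
        np.testing.assert_allclose(grid.values.data, 0.7)

    def test_overlapping_kernel_matches_naive_windows(self, rng):
        """Kernel 4 / stride 2 embedding equals padded sliding-window dots."""
        img = rng.uniform(size=(1, 2, 8, 8))
        w = rng.normal(size=(5, 2, 4, 4))
        grid = conv_patch_embed(Tensor(img), Tensor(w), None, stride=2)
        assert (grid.h, grid.w) == (4, 4)
        padded = np.pad(img, ((0, 0), (0, 0), (1, 1), (1, 1)))
        for i in range(4):
            for j in range(4):
                patch = padded[0, :, 2 * i:2 * i + 4, 2 * j:2 * j + 4]
                expected = np.array([(patch * w[o]).sum() for o in range(5)])
                np.testing.assert_allclose(
                    grid.values.data[0, i * 4 + j], expected, atol=1e-12)

    def test_indivisible_dims_rejected(self, rng):
        img = rng.uniform(size=(1, 3, 10, 10))
        w = rng.normal(size=(4, 3, 4, 4))
        with pytest.raises(ValueError):
            conv_patch_embed(Tensor(img), Tensor(w), None, stride=4)


class TestPositionalEncoding:
    def test_zero_encoding_is_identity(self, rng):
        grid = TokenGrid(Tensor(rng.normal(size=(2, 9, 4))), 3, 3)
        out = add_positional_encoding(grid, Tensor(np.zeros((9, 4))))
        np.testing.assert_array_equal(out.values.data, grid.values.data)

    def test_add_then_subtract_recovers_tokens(self, rng):
        grid = TokenGrid(Tensor(rng.normal(size=(1, 9, 4))), 3, 3)
        pe = rng.normal(size=(9, 4))
        out = add_positional_encoding(
            add_positional_encoding(grid, Tensor(pe)), Tensor(-pe))
        np.testing.assert_allclose(out.values.data, grid.values.data, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        grid = TokenGrid(Tensor(rng.normal(size=(1, 9, 4))), 3, 3)
        with pytest.raises(ValueError):
            add_positional_encoding(grid, Tensor(np.zeros((4, 4))))


class TestSpatialBias:
    def test_zero_table_gives_zero_matrix(self):
        table = SpatialBiasTable(heads=3, scope_h=2, scope_w=2)
        s = table.matrix()
        assert s.shape == (3, 4, 4)
        np.testing.assert_array_equal(s.data, 0.0)

    def test_two_by_two_scope_references_nine_offsets(self):
        """All pairs on a 2x2 grid realize exactly the 3x3 offset set."""
        idx = relative_position_index(2, 2)
        offsets = set()
        for i in range(4):
            for j in range(4):
                ri, ci = divmod(i, 2)
                rj, cj = divmod(j, 2)
                offsets.add((ri - rj, ci - cj))
        assert len(offsets) == 9
        assert len(np.unique(idx)) == 9

    def test_bias_depends_only_on_relative_offset(self, rng):
        table = SpatialBiasTable(heads=1, scope_h=3, scope_w=3)
        table.table.data = rng.normal(size=table.table.shape)
        s = table.matrix().data[0]
        rows, cols = np.divmod(np.arange(9), 3)
        for i in range(9):
            for j in range(9):
                for k in range(9):
                    for l in range(9):
                        if (rows[i] - rows[j], cols[i] - cols[j]) == \
                           (rows[k] - rows[l], cols[k] - cols[l]):
                            assert s[i, j] == s[k, l]

    def test_scope_overflow_rejected(self):
        table = SpatialBiasTable(heads=1, scope_h=2, scope_w=2)
        with pytest.raises(IndexError):
            relative_spatial_bias((3, 3), table)


class TestBiasedAttention:
    def test_single_token_passthrough(self, rng):
        cfg = AttentionConfig(heads=1, head_dim=4)
        proj = make_proj(4, cfg, rng)
        x = rng.normal(size=(1, 1, 4))
        out = biased_attention(Tensor(x), proj, None, cfg)
        expected = (x[0] @ proj.w_v.weight.data) @ proj.w_out.weight.data \
            + proj.w_out.bias.data
        np.testing.assert_allclose(out.data[0], expected, atol=1e-12)

    @pytest.mark.parametrize("n,heads,head_dim", [(3, 1, 2), (4, 2, 3), (9, 2, 2)])
    def test_matches_explicit_loop_oracle(self, rng, n, heads, head_dim):
        dim = heads * head_dim
        cfg = AttentionConfig(heads=heads, head_dim=head_dim)
        proj = make_proj(dim, cfg, rng)
        proj.w_out.bias.data[:] = 0
        x = rng.normal(size=(1, n, dim))
        bias = rng.normal(size=(heads, n, n))
        out = biased_attention(Tensor(x), proj, Tensor(bias), cfg)
        expected = naive_attention(x[0], proj.w_q.weight.data,
                                   proj.w_k.weight.data, proj.w_v.weight.data,
                                   proj.w_out.weight.data, heads, head_dim,
                                   bias)
        np.testing.assert_allclose(out.data[0], expected, atol=1e-6)

    def test_softmax_shift_invariance(self, rng):
        cfg = AttentionConfig(heads=1, head_dim=2)
        proj = make_proj(2, cfg, rng)
        x = rng.normal(size=(1, 4, 2))
        base = attention_weights(Tensor(x), proj, None, cfg)
        shifted_bias = np.full((1, 4, 4), 3.7)  # constant added to each row
        shifted = attention_weights(Tensor(x), proj, Tensor(shifted_bias), cfg)
        np.testing.assert_allclose(base, shifted, atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        cfg = AttentionConfig(heads=2, head_dim=3)
        proj = make_proj(6, cfg, rng)
        x = rng.normal(size=(2, 5, 6)) * 4
        w = attention_weights(Tensor(x), proj, None, cfg)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-10)

    def test_non_finite_input_rejected(self, rng):
        cfg = AttentionConfig(heads=1, head_dim=2)
        proj = make_proj(2, cfg, rng)
        bad = np.full((1, 2, 2), np.nan)
        with pytest.raises(ValueError):
            biased_attention(Tensor(bad), proj, None, cfg)


class TestWindowing:
    def test_single_window_when_m_equals_grid(self, rng):
        grid = TokenGrid(Tensor(rng.normal(size=(1, 16, 3))), 4, 4)
        wins = window_partition(grid, 4)
        assert wins.shape == (1, 16, 3)

    def test_four_windows_on_4x4_grid(self, rng):
        grid = TokenGrid(Tensor(rng.normal(size=(2, 16, 3))), 4, 4)
        wins = window_partition(grid, 2)
        assert wins.shape == (8, 4, 3)

    def test_partition_reverse_identity(self, rng):
        grid = TokenGrid(Tensor(rng.normal(size=(3, 36, 5))), 6, 6)
        back = window_reverse(window_partition(grid, 3), 3, 6, 6, 3)
        np.testing.assert_array_equal(back.values.data, grid.values.data)

    def test_window_content_is_contiguous_tile(self, rng):
        vals = np.arange(16.0).reshape(1, 16, 1)
        grid = TokenGrid(Tensor(vals), 4, 4)
        wins = window_partition(grid, 2).data[:, :, 0]
        np.testing.assert_array_equal(wins[0], [0, 1, 4, 5])  # top-left tile

    def test_indivisible_window_rejected(self, rng):
        grid = TokenGrid(Tensor(rng.normal(size=(1, 36, 2))), 6, 6)
        with pytest.raises(ValueError):
            window_partition(grid, 4)


class TestTransformerBlocks:
    def test_esla_preserves_shape(self, rng):
        cfg = AttentionConfig(heads=2, head_dim=4, window_size=2)
        block = ESLABlock(8, (4, 4), cfg, rng)
        grid = TokenGrid(Tensor(rng.normal(size=(2, 16, 8))), 4, 4)
        out = block(grid)
        assert (out.h, out.w, out.d) == (4, 4, 8)

    def test_esla_full_window_equals_esga(self, rng):
        """Local attention with a full-grid window is global attention."""
        cfg = AttentionConfig(heads=2, head_dim=3, window_size=4)
        esla = ESLABlock(6, (4, 4), cfg, np.random.default_rng(77))
        esga = ESGABlock(6, (4, 4), cfg, np.random.default_rng(77))
        x = rng.normal(size=(2, 16, 6))
        a = esla(TokenGrid(Tensor(x), 4, 4)).values.data
        b = esga(TokenGrid(Tensor(x), 4, 4)).values.data
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_esga_zero_bias_matches_plain_block_oracle(self, rng):
        """With a zero bias table the block is a plain pre-norm transformer."""
        cfg = AttentionConfig(heads=1, head_dim=4)
        block = ESGABlock(4, (2, 2), cfg, rng)
        x = rng.normal(size=(1, 4, 4))

        def reference(tokens):
            def ln(v, gamma, beta, eps=1e-6):
                mu = v.mean(-1, keepdims=True)
                var = ((v - mu) ** 2).mean(-1, keepdims=True)
                return (v - mu) / np.sqrt(var + eps) * gamma + beta

            normed = ln(tokens, block.norm1.gamma.data, block.norm1.beta.data)
            att = naive_attention(normed, block.proj.w_q.weight.data,
                                  block.proj.w_k.weight.data,
                                  block.proj.w_v.weight.data,
                                  block.proj.w_out.weight.data, 1, 4)
            att = att + block.proj.w_out.bias.data
            y = tokens + att
            normed2 = ln(y, block.norm2.gamma.data, block.norm2.beta.data)
            h = normed2 @ block.mlp.fc1.weight.data + block.mlp.fc1.bias.data
            c = math.sqrt(2 / math.pi)
            h = 0.5 * h * (1 + np.tanh(c * (h + 0.044715 * h ** 3)))
            return y + h @ block.mlp.fc2.weight.data + block.mlp.fc2.bias.data

        out = block(TokenGrid(Tensor(x), 2, 2)).values.data
        np.testing.assert_allclose(out[0], reference(x[0]), atol=1e-8)

    def test_every_parameter_receives_gradient(self, rng):
        cfg = AttentionConfig(heads=2, head_dim=2, window_size=2)
        block = ESLABlock(4, (4, 4), cfg, rng)
        grid = TokenGrid(Tensor(rng.normal(size=(1, 16, 4))), 4, 4)
        (block(grid).values ** 2.0).sum().backward()
        for name, p in block.named_parameters():
            assert p.grad is not None and np.abs(p.grad).max() > 0, name


class TestCrossAndSkipAttention:
    def test_single_encoder_token_passthrough(self, rng):
        cfg = AttentionConfig(heads=1, head_dim=4)
        mod = CrossAttention(dec_dim=4, enc_dim=6, cfg=cfg, rng=rng)
        dec = TokenGrid(Tensor(rng.normal(size=(1, 4, 4))), 2, 2)
        enc = TokenGrid(Tensor(rng.normal(size=(1, 1, 6))), 1, 1)
        out = mod(dec, enc)
        expected = (enc.values.data[0] @ mod.proj.w_v.weight.data) \
            @ mod.proj.w_out.weight.data + mod.proj.w_out.bias.data
        for i in range(4):
            np.testing.assert_allclose(out.values.data[0, i], expected[0],
                                       atol=1e-12)

    def test_matches_explicit_loop_oracle(self, rng):
        cfg = AttentionConfig(heads=1, head_dim=3)
        mod = CrossAttention(dec_dim=3, enc_dim=3, cfg=cfg, rng=rng)
        mod.proj.w_out.bias.data[:] = 0
        dec = rng.normal(size=(2, 3))
        enc = rng.normal(size=(3, 3))
        out = mod(TokenGrid(Tensor(dec[None]), 1, 2),
                  TokenGrid(Tensor(enc[None]), 1, 3))
        q = dec @ mod.proj.w_prime.weight.data
        k = enc @ mod.proj.w_k.weight.data
        v = enc @ mod.proj.w_v.weight.data
        expected = np.zeros((2, 3))
        for i in range(2):
            scores = np.array([q[i] @ k[j] / math.sqrt(3) for j in range(3)])
            e = np.exp(scores - scores.max())
            a = e / e.sum()
            expected[i] = sum(a[j] * v[j] for j in range(3)) \
                @ mod.proj.w_out.weight.data
        np.testing.assert_allclose(out.values.data[0], expected, atol=1e-10)

    def test_cross_rows_sum_to_one(self, rng):
        cfg = AttentionConfig(heads=2, head_dim=2)
        mod = CrossAttention(dec_dim=4, enc_dim=4, cfg=cfg, rng=rng)
        dec = Tensor(rng.normal(size=(1, 4, 4)))
        enc = Tensor(rng.normal(size=(1, 9, 4)))
        w = attention_weights(dec, mod.proj, None, cfg, kv_tokens=enc)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-10)

    def test_zero_value_projection_leaves_decoder_unchanged(self, rng):
        cfg = AttentionConfig(heads=1, head_dim=4)
        fuse = SkipAttentionFuse(4, 4, cfg, rng)
        fuse.cross.proj.w_v.weight.data[:] = 0
        fuse.cross.proj.w_out.bias.data[:] = 0
        dec = TokenGrid(Tensor(rng.normal(size=(1, 4, 4))), 2, 2)
        enc = TokenGrid(Tensor(rng.normal(size=(1, 4, 4))), 2, 2)
        out = fuse(dec, enc)
        np.testing.assert_allclose(out.values.data, dec.values.data, atol=1e-12)

    def test_gradient_reaches_both_streams(self, rng):
        cfg = AttentionConfig(heads=1, head_dim=4)
        fuse = SkipAttentionFuse(4, 4, cfg, rng)
        dec = Tensor(rng.normal(size=(1, 4, 4)), requires_grad=True)
        enc = Tensor(rng.normal(size=(1, 4, 4)), requires_grad=True)
        out = fuse(TokenGrid(dec, 2, 2), TokenGrid(enc, 2, 2))
        (out.values ** 2.0).sum().backward()
        assert dec.grad is not None and np.abs(dec.grad).max() > 0
        assert enc.grad is not None and np.abs(enc.grad).max() > 0

    def test_resolution_mismatch_rejected(self, rng):
        cfg = AttentionConfig(heads=1, head_dim=4)
        fuse = SkipAttentionFuse(4, 4, cfg, rng)
        dec = TokenGrid(Tensor(rng.normal(size=(1, 4, 4))), 2, 2)
        enc = TokenGrid(Tensor(rng.normal(size=(1, 9, 4))), 3, 3)
        with pytest.raises(ValueError):
            fuse(dec, enc)
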