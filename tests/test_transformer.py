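"""Attention machinery: tokenization, positional encoding, MHSA, FFN."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from strokeseg import nn
from strokeseg.attention import (FeedForward, MultiHeadSelfAttention,
                                 TokenEncoderLayer, TransformerBlock2d,
                                 detokenize, ffn, mhsa, positional_encoding,
                                 tokenize)
from strokeseg.nn import Tensor


def _rng(seed=0):
    return np.random.default_rng(seed)


def mhsa_oracle(x: np.ndarray, layer: MultiHeadSelfAttention) -> np.ndarray:
    """Brute force: loop over heads and tokens, explicit softmax rows."""
    t, d = x.shape
    h, dh = layer.heads, layer.head_dim
    q = x @ layer.wq.weight.data + layer.wq.bias.data
    k = x @ layer.wk.weight.data + layer.wk.bias.data
    v = x @ layer.wv.weight.data + layer.wv.bias.data
    heads_out = []
    for i in range(h):
        qi = q[:, i * dh:(i + 1) * dh]
        ki = k[:, i * dh:(i + 1) * dh]
        vi = v[:, i * dh:(i + 1) * dh]
        out_i = np.zeros_like(qi)
        for a in range(t):
            scores = np.array([qi[a] @ ki[b] for b in range(t)]) / np.sqrt(dh)
            e = np.exp(scores - scores.max())
            w = e / e.sum()
            out_i[a] = sum(w[b] * vi[b] for b in range(t))
        heads_out.append(out_i)
    merged = np.concatenate(heads_out, axis=1)
    return merged @ layer.wo.weight.data + layer.wo.bias.data


class TestTokenize:
    def test_token_counts(self, rng):
        x = rng.random((1, 4, 4, 8), dtype=np.float32)
        assert tokenize(x, 1).shape == (1, 16, 8)
        assert tokenize(x, 2).shape == (1, 4, 32)

    def test_round_trip_identity(self, rng):
        x = rng.random((2, 6, 6, 5), dtype=np.float32)
        for patch in (1, 2, 3):
            back = detokenize(tokenize(x, patch), 6, 6, patch)
            np.testing.assert_array_equal(back.data, x)

    def test_non_divisible_dims_rejected(self, rng):
        x = rng.random((1, 6, 6, 2), dtype=np.float32)
        with pytest.raises(ValueError, match="divisible"):
            tokenize(x, 4)


class TestPositionalEncoding:
    def test_position_zero_alternates_zero_one(self):
        table = positional_encoding(4, 8)
        np.testing.assert_allclose(table[0], [0, 1] * 4, atol=1e-12)

    def test_values_bounded(self):
        table = positional_encoding(500, 64)
        assert table.min() >= -1.0 and table.max() <= 1.0

    def test_rows_pairwise_distinct(self):
        table = positional_encoding(1000, 32)
        diffs = np.abs(table[:, None, :] - table[None, :, :]).max(axis=-1)
        diffs[np.diag_indices(1000)] = np.inf
        assert diffs.min() > 1e-6

    def test_odd_dim_rejected(self):
        with pytest.raises(ValueError, match="even"):
            positional_encoding(10, 7)


class TestMHSA:
    def test_single_token_returns_value_projection(self, rng):
        layer = MultiHeadSelfAttention(8, 2, _rng(3))
        x = rng.standard_normal((1, 8)).astype(np.float32)
        out = mhsa(x, layer)
        v = x @ layer.wv.weight.data + layer.wv.bias.data
        expected = v @ layer.wo.weight.data + layer.wo.bias.data
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_duplicated_tokens_give_duplicated_outputs(self, rng):
        layer = MultiHeadSelfAttention(6, 2, _rng(4))
        tok = rng.standard_normal(6).astype(np.float32)
        x = np.stack([tok, tok, tok])
        out = mhsa(x, layer)
        np.testing.assert_allclose(out[0], out[1], atol=1e-6)
        np.testing.assert_allclose(out[0], out[2], atol=1e-6)

    @pytest.mark.parametrize("heads", [1, 2, 4])
    @pytest.mark.parametrize("tokens", [2, 5, 8])
    def test_matches_brute_force_oracle(self, heads, tokens):
        rng = _rng(heads * 10 + tokens)
        layer = MultiHeadSelfAttention(8, heads, rng)
        x = rng.standard_normal((tokens, 8)).astype(np.float32)
        np.testing.assert_allclose(mhsa(x, layer), mhsa_oracle(x, layer),
                                   atol=1e-5)

    def test_attention_rows_are_probability_vectors(self, rng):
        layer = MultiHeadSelfAttention(8, 4, _rng(5))
        x = rng.standard_normal((1, 7, 8)).astype(np.float32)
        with nn.no_grad():
            layer(Tensor(x))
        sums = layer.last_attention.sum(axis=-1)
        np.testing.assert_allclose(sums, np.ones_like(sums), atol=1e-6)

    def test_dimension_mismatch_rejected(self, rng):
        layer = MultiHeadSelfAttention(8, 2, _rng(6))
        with pytest.raises(ValueError, match="sequence"):
            layer(Tensor(rng.standard_normal((1, 3, 5))))

    def test_permutation_equivariance_without_positions(self, rng):
        layer = MultiHeadSelfAttention(6, 3, _rng(8))
        x = rng.standard_normal((5, 6)).astype(np.float32)
        perm = np.array([3, 1, 4, 0, 2])
        np.testing.assert_allclose(mhsa(x, layer)[perm],
                                   mhsa(x[perm], layer), atol=1e-5)


class TestFFN:
    def test_zero_weights_give_constant_bias(self):
        d, h = 4, 6
        out = ffn(np.zeros((3, d)) - 1.0, np.zeros((d, h)), np.zeros(h),
                  np.zeros((h, d)), np.full(d, 2.5))
        np.testing.assert_allclose(out, np.full((3, d), 2.5))

    def test_relu_dead_zone(self):
        d = 3
        x = -np.abs(np.random.default_rng(0).standard_normal((4, d)))
        b2 = np.array([1.0, -2.0, 3.0])
        out = ffn(x, np.eye(d), np.zeros(d), np.eye(d), b2)
        np.testing.assert_allclose(out, np.tile(b2, (4, 1)))

    def test_matches_elementwise_loop_oracle(self, rng):
        d, h, t = 5, 7, 6
        w1 = rng.standard_normal((d, h))
        b1 = rng.standard_normal(h)
        w2 = rng.standard_normal((h, d))
        b2 = rng.standard_normal(d)
        x = rng.standard_normal((t, d))
        expected = np.empty((t, d))
        for a in range(t):
            hidden = [max(0.0, sum(x[a][j] * w1[j][m] for j in range(d))
                          + b1[m]) for m in range(h)]
            for out_j in range(d):
                expected[a][out_j] = sum(hidden[m] * w2[m][out_j]
                                         for m in range(h)) + b2[out_j]
        np.testing.assert_allclose(ffn(x, w1, b1, w2, b2), expected,
                                   atol=1e-10)

    def test_identical_tokens_map_identically(self, rng):
        layer = FeedForward(4, 9, _rng(2))
        tok = rng.standard_normal(4).astype(np.float32)
        with nn.no_grad():
            out = layer(Tensor(np.stack([tok, tok])[None])).data[0]
        np.testing.assert_allclose(out[0], out[1], atol=1e-6)


class TestTransformerBlock:
    def test_shape_preserving(self, rng):
        blk = TransformerBlock2d(6, 2, embed_dim=8, heads=2, ffn_dim=12,
                                 rng=_rng(1))
        blk.eval()
        x = rng.random((1, 8, 8, 6), dtype=np.float32)
        with nn.no_grad():
            out = blk(Tensor(x))
        assert out.shape == x.shape
        assert np.all(np.isfinite(out.data))

    def test_post_norm_sublayer_statistics(self, rng):
        layer = TokenEncoderLayer(16, 2, 24, _rng(2), norm_placement="post")
        layer.eval()
        x = rng.standard_normal((1, 10, 16)).astype(np.float32)
        with nn.no_grad():
            out = layer(Tensor(x)).data
        np.testing.assert_allclose(out.mean(axis=-1), 0.0, atol=1e-4)
        np.testing.assert_allclose(out.var(axis=-1), 1.0, atol=1e-2)

    def test_zero_output_projections_reduce_to_normalised_identity(self, rng):
        layer = TokenEncoderLayer(8, 2, 12, _rng(3), norm_placement="post")
        layer.attn.wo.weight.data[:] = 0.0
        layer.attn.wo.bias.data[:] = 0.0
        layer.ffn.lin2.weight.data[:] = 0.0
        layer.ffn.lin2.bias.data[:] = 0.0
        layer.eval()
        x = rng.standard_normal((1, 5, 8)).astype(np.float32)
        with nn.no_grad():
            out = layer(Tensor(x)).data
            expected = layer.norm2(layer.norm1(Tensor(x))).data
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_positional_encoding_breaks_permutation_symmetry(self, rng):
        x = rng.random((1, 4, 4, 6), dtype=np.float32)
        perm = np.random.default_rng(5).permutation(16)

        def run(use_pe):
            blk = TransformerBlock2d(6, 1, embed_dim=8, heads=2, ffn_dim=12,
                                     rng=_rng(7), use_positional_encoding=use_pe)
            blk.eval()
            with nn.no_grad():
                tok = tokenize(Tensor(x), 1)
                out_plain = blk(Tensor(x)).data
                xp = detokenize(Tensor(tok.data[:, perm, :]), 4, 4, 1).data
                out_perm = blk(Tensor(xp)).data
            flat = tokenize(Tensor(out_plain), 1).data[:, perm, :]
            flat_perm = tokenize(Tensor(out_perm), 1).data
            return np.allclose(flat, flat_perm, atol=1e-5)

        assert run(False)       # equivariant without positions
        assert not run(True)    # broken by positional offsets


@given(heads=st.sampled_from([1, 2, 4]), tokens=st.integers(1, 8))
def test_mhsa_oracle_property(heads, tokens):
    rng = _rng(heads * 100 + tokens)
    layer = MultiHeadSelfAttention(8, heads, rng)
    x = rng.standard_normal((tokens, 8)).astype(np.float32)
    np.testing.assert_allclose(mhsa(x, layer), mhsa_oracle(x, layer),
                               atol=1e-5)
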