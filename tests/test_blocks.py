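"""Shape algebra, receptive field and degeneracy checks for the conv blocks."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from strokeseg import nn
from strokeseg.blocks import (DDBConfig, DenseBlock, DilatedBlock,
                              DilatedDenseBlock, StemBlock, TransitionConfig,
                              TransitionLayer, UpsampleBlock, dense_block,
                              dilated_block, stem, transition_layer, upsample)
from strokeseg.nn import Tensor


def _rng():
    return np.random.default_rng(0)


class TestStem:
    def test_output_shape_contract(self, rng):
        x = rng.random((192, 192, 1), dtype=np.float32)
        assert stem(x, 32).shape == (192, 192, 32)
        x = rng.random((64, 64, 1), dtype=np.float32)
        assert stem(x, 8).shape == (64, 64, 8)

    def test_multichannel_input_rejected(self, rng):
        x = rng.random((32, 32, 4), dtype=np.float32)
        with pytest.raises(ValueError, match="single-modality"):
            stem(x, 8)
        with pytest.raises(ValueError, match="single-modality"):
            StemBlock(8, _rng(), in_channels=4)


class TestDilatedBlock:
    def test_receptive_field_support_width(self):
        """The impulse response of the (2, 4, 8) stack spans 1 + 2*14 = 29
        pixels along each axis."""
        cfg = DDBConfig(dilated_channels=2, dilation_rates=(2, 4, 8),
                        dense_layers=1, growth=1, dropout=0.0)
        block = DilatedBlock(1, cfg, _rng())
        # positive weights so ReLU never cancels the response
        for conv in block.layers:
            conv.weight.data = np.abs(conv.weight.data) + 1e-3
        block.eval()
        n = 64
        x = np.zeros((1, n, n, 1), dtype=np.float32)
        x[0, n // 2, n // 2, 0] = 1.0
        with nn.no_grad():
            out = block(Tensor(x)).data[0].sum(axis=-1)
        rows = np.where(out.sum(axis=1) > 0)[0]
        cols = np.where(out.sum(axis=0) > 0)[0]
        assert rows[-1] - rows[0] + 1 == cfg.receptive_field == 29
        assert cols[-1] - cols[0] + 1 == 29

    def test_zero_input_zero_biases_gives_zero_output(self):
        cfg = DDBConfig(dilated_channels=3, dropout=0.0)
        x = np.zeros((48, 48, 2), dtype=np.float32)
        out = dilated_block(x, cfg)
        np.testing.assert_array_equal(out, np.zeros((48, 48, 3)))

    def test_spatial_dims_preserved(self, rng):
        cfg = DDBConfig(dilated_channels=5, dropout=0.0)
        x = rng.random((48, 48, 7), dtype=np.float32)
        assert dilated_block(x, cfg).shape == (48, 48, 5)


class TestDenseBlock:
    def test_channel_growth_examples(self, rng):
        cfg = DDBConfig(dilated_channels=32, dense_layers=4, growth=16,
                        dropout=0.0)
        x = rng.random((8, 8, 32), dtype=np.float32)
        assert dense_block(x, cfg).shape[-1] == 32 + 4 * 16 == 96

    def test_degenerate_layer_count_rejected(self):
        with pytest.raises(ValueError, match="dense_layers"):
            DDBConfig(dense_layers=0)

    def test_concatenation_keeps_input_first(self, rng):
        """Channel 0..C-1 of the output stack are the block input itself."""
        cfg = DDBConfig(dilated_channels=8, dense_layers=1, growth=4,
                        dropout=0.0)
        block = DenseBlock(8, cfg, _rng())
        block.eval()
        x = rng.random((1, 6, 6, 8), dtype=np.float32)
        with nn.no_grad():
            out = block(Tensor(x)).data
        assert out.shape[-1] == 12
        np.testing.assert_allclose(out[..., :8], x, atol=1e-6)

    @given(c=st.integers(1, 12), layers=st.integers(1, 4),
           growth=st.integers(1, 8))
    def test_channel_algebra_property(self, c, layers, growth):
        cfg = DDBConfig(dilated_channels=max(c, 1), dense_layers=layers,
                        growth=growth, dropout=0.0)
        block = DenseBlock(c, cfg, _rng())
        assert block.out_channels == c + layers * growth


class TestDDB:
    def test_composition_is_dilated_then_dense(self, rng):
        cfg = DDBConfig(dilated_channels=6, dense_layers=2, growth=3,
                        dropout=0.0)
        ddb = DilatedDenseBlock(4, cfg, _rng())
        ddb.eval()
        x = rng.random((1, 16, 16, 4), dtype=np.float32)
        with nn.no_grad():
            via_ddb = ddb(Tensor(x)).data
            via_parts = ddb.dense(ddb.dilated(Tensor(x))).data
        np.testing.assert_array_equal(via_ddb, via_parts)

    def test_shape_arithmetic(self, rng):
        cfg = DDBConfig(dilated_channels=10, dense_layers=3, growth=4,
                        dropout=0.0)
        ddb = DilatedDenseBlock(5, cfg, _rng())
        ddb.eval()
        x = rng.random((1, 32, 32, 5), dtype=np.float32)
        with nn.no_grad():
            out = ddb(Tensor(x)).data
        assert out.shape == (1, 32, 32, 10 + 3 * 4)
        assert np.all(np.isfinite(out))

    def test_deterministic_under_fixed_seed(self, rng):
        cfg = DDBConfig(dilated_channels=4, dense_layers=2, growth=2,
                        dropout=0.0)
        x = rng.random((1, 8, 8, 3), dtype=np.float32)
        outs = []
        for _ in range(2):
            blk = DilatedDenseBlock(3, cfg, np.random.default_rng(99))
            blk.eval()
            with nn.no_grad():
                outs.append(blk(Tensor(x)).data)
        np.testing.assert_array_equal(outs[0], outs[1])


class TestTransition:
    def test_compression_and_halving(self, rng):
        x = rng.random((48, 48, 96), dtype=np.float32)
        out = transition_layer(x, TransitionConfig(compression=0.5))
        assert out.shape == (24, 24, 48)

    def test_identity_compression_keeps_channels(self, rng):
        x = rng.random((16, 16, 10), dtype=np.float32)
        out = transition_layer(x, TransitionConfig(compression=1.0))
        assert out.shape == (8, 8, 10)

    def test_odd_spatial_dims_rejected(self, rng):
        x = rng.random((47, 47, 4), dtype=np.float32)
        with pytest.raises(ValueError, match="even"):
            transition_layer(x, TransitionConfig())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TransitionConfig(compression=0.0)
        with pytest.raises(ValueError):
            TransitionConfig(stride=3)


class TestUpsample:
    def test_shape_contract(self, rng):
        x = rng.random((24, 24, 8), dtype=np.float32)
        assert upsample(x).shape == (48, 48, 4)

    def test_round_trip_with_transition_restores_dims(self, rng):
        x = rng.random((16, 16, 8), dtype=np.float32)
        down = transition_layer(x, TransitionConfig())
        up = upsample(down)
        assert up.shape[:2] == x.shape[:2]

    def test_checkerboard_replication_before_conv(self):
        blk = UpsampleBlock(2, _rng())
        # identity 1x1 conv on channel 0 isolates the interpolation step
        blk.conv.weight.data = np.zeros_like(blk.conv.weight.data)
        blk.conv.weight.data[0, 0, 0, 0] = 1.0
        blk.eval()
        checker = np.indices((2, 2)).sum(axis=0) % 2
        x = np.zeros((1, 2, 2, 2), dtype=np.float32)
        x[0, :, :, 0] = checker
        with nn.no_grad():
            out = blk(Tensor(x)).data[0, :, :, 0]
        np.testing.assert_array_equal(out, checker.repeat(2, 0).repeat(2, 1))


@given(rates=st.lists(st.integers(1, 16), min_size=1, max_size=4,
                      unique=True).map(sorted))
def test_receptive_field_formula(rates):
    cfg = DDBConfig(dilation_rates=tuple(rates))
    assert cfg.receptive_field == 1 + 2 * sum(rates)


def test_strictly_increasing_rates_enforced():
    with pytest.raises(ValueError, match="strictly increasing"):
        DDBConfig(dilation_rates=(2, 2, 4))
    with pytest.raises(ValueError, match="strictly increasing"):
        DDBConfig(dilation_rates=(4, 2))
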