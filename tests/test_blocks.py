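"""Unit tests of the computational blocks."""

import numpy as np
import pytest

from madrnet import (ASPP, AttentionConfig, ChannelAttention, ConvUnit, CSAM,
                     DilationSpec, MultiDilatedResidualBlock, SpatialAttention,
                     effective_kernel_size)
from madrnet.autograd import Tensor

from oracles import (aspp_oracle, batchnorm_eval_oracle, conv2d_oracle,
                     sigmoid_oracle, spatial_attention_oracle)


def zero_params(module):
    for p in module.parameters():
        p.data = np.zeros_like(p.data)


# ------------------------------------------------------- effective kernel size
def test_effective_kernel_size_values():
    assert effective_kernel_size(3, 1) == 3
    assert effective_kernel_size(3, 5) == 11
    assert effective_kernel_size(1, 7) == 1
    assert effective_kernel_size(DilationSpec(3, 3)) == 7


def test_effective_kernel_size_monotone_in_dilation():
    for k in (3, 5, 7, 9):
        sizes = [effective_kernel_size(k, d) for d in range(1, 10)]
        assert sizes[0] == k
        assert all(a < b for a, b in zip(sizes, sizes[1:]))


def test_effective_kernel_size_rejects_nonpositive():
    with pytest.raises(ValueError):
        effective_kernel_size(0, 1)
    with pytest.raises(ValueError):
        effective_kernel_size(3, 0)


def test_dilation_spec_requires_odd_kernel():
    with pytest.raises(ValueError):
        DilationSpec(4, 1)


# ------------------------------------------------------------------- conv unit
def test_conv_unit_shape_contract(rng):
    unit = ConvUnit(8, 16, DilationSpec(3, 3), rng=rng)
    out = unit(Tensor(np.random.default_rng(0).normal(size=(2, 8, 16, 16))))
    assert out.shape == (2, 16, 16, 16)


def test_conv_unit_zero_weights_gives_zero(rng):
    unit = ConvUnit(4, 4, rng=rng)
    unit.conv.weight.data[:] = 0
    unit.conv.bias.data[:] = 0
    out = unit(Tensor(np.random.default_rng(0).normal(size=(1, 4, 8, 8))))
    assert np.all(out.numpy() == 0)


def test_conv_unit_matches_straight_loop_oracle(rng):
    unit = ConvUnit(3, 5, DilationSpec(3, 2), rng=rng).eval()
    x = np.random.default_rng(3).normal(size=(2, 3, 8, 8)).astype(np.float32)
    got = unit(Tensor(x)).numpy()
    bn = unit.bn
    normed = batchnorm_eval_oracle(x, bn.running_mean, bn.running_var,
                                   bn.weight.data, bn.bias.data, bn.eps)
    ref = conv2d_oracle(np.maximum(normed, 0.0), unit.conv.weight.data,
                        unit.conv.bias.data, dilation=2)
    np.testing.assert_allclose(got, ref, atol=1e-5)


# -------------------------------------------------------------- residual block
def test_residual_block_shape(rng):
    block = MultiDilatedResidualBlock(4, 8, rng=rng)
    out = block(Tensor(np.random.default_rng(0).normal(size=(1, 4, 16, 16))))
    assert out.shape == (1, 8, 16, 16)


def test_residual_block_zero_weights_is_identity(rng):
    block = MultiDilatedResidualBlock(6, 6, rng=rng)
    zero_params(block)
    # batch-norm scale parameters restored so the units are well-defined;
    # the convolution weights stay zero, killing every branch
    for m in block.modules():
        if hasattr(m, "running_var"):
            m.weight.data[:] = 1
    x = np.random.default_rng(0).normal(size=(2, 6, 8, 8)).astype(np.float32)
    out = block(Tensor(x)).numpy()
    np.testing.assert_array_equal(out, x)


def test_residual_block_single_branch_oracle(rng):
    """rates=[1], one conv per branch: plain pre-activation residual block."""
    block = MultiDilatedResidualBlock(3, 3, rates=(1,), convs_per_branch=1,
                                      rng=rng).eval()
    x = np.random.default_rng(5).normal(size=(1, 3, 8, 8)).astype(np.float32)
    got = block(Tensor(x)).numpy()
    unit = block.branches[0][0]
    bn = unit.bn
    normed = batchnorm_eval_oracle(x, bn.running_mean, bn.running_var,
                                   bn.weight.data, bn.bias.data, bn.eps)
    branch = conv2d_oracle(np.maximum(normed, 0.0), unit.conv.weight.data,
                           unit.conv.bias.data, dilation=1)
    np.testing.assert_allclose(got, x + branch, atol=1e-5)


def test_residual_block_uses_projection_on_channel_change(rng):
    assert MultiDilatedResidualBlock(4, 8, rng=rng).projection is not None
    assert MultiDilatedResidualBlock(8, 8, rng=rng).projection is None


def test_residual_block_rejects_empty_rates(rng):
    with pytest.raises(ValueError):
        MultiDilatedResidualBlock(4, 4, rates=(), rng=rng)


# ------------------------------------------------------------------------ aspp
def test_aspp_shape_at_bottleneck_resolution(rng):
    aspp = ASPP(32, 32, rng=rng)
    out = aspp(Tensor(np.random.default_rng(0).normal(size=(1, 32, 4, 4))))
    assert out.shape == (1, 32, 4, 4)


def test_aspp_branch_count():
    assert ASPP(8, 8, rng=np.random.default_rng(0)).n_branches == 5
    assert ASPP(8, 8, rates=(2, 4), rng=np.random.default_rng(0)).n_branches == 4


def test_aspp_zero_weights_gives_zero(rng):
    aspp = ASPP(4, 4, rng=rng)
    zero_params(aspp)
    out = aspp(Tensor(np.full((1, 4, 6, 6), 3.0)))
    assert np.all(out.numpy() == 0)


def test_aspp_matches_branchwise_oracle(rng):
    aspp = ASPP(3, 4, rates=(2, 3), rng=rng)
    x = np.random.default_rng(9).normal(size=(2, 3, 8, 8)).astype(np.float32)
    np.testing.assert_allclose(aspp(Tensor(x)).numpy(), aspp_oracle(x, aspp),
                               atol=1e-5)


def test_aspp_well_defined_below_effective_kernel(rng):
    # spatial extent far smaller than the largest dilated kernel footprint
    aspp = ASPP(4, 4, rng=rng)
    out = aspp(Tensor(np.random.default_rng(0).normal(size=(1, 4, 2, 2))))
    assert out.shape == (1, 4, 2, 2)
    assert np.all(np.isfinite(out.numpy()))


# ------------------------------------------------------------------- attention
def test_channel_attention_shape_and_range(rng):
    att = ChannelAttention(32, rng=rng)
    out = att(Tensor(np.random.default_rng(0).normal(size=(2, 32, 8, 8)))).numpy()
    assert out.shape == (2, 32, 1, 1)
    assert np.all((out > 0) & (out < 1))


def test_channel_attention_zero_weights_gives_half(rng):
    att = ChannelAttention(16, rng=rng)
    zero_params(att)
    out = att(Tensor(np.random.default_rng(0).normal(size=(3, 16, 4, 4)))).numpy()
    np.testing.assert_array_equal(out, np.full((3, 16, 1, 1), 0.5, np.float32))


def test_channel_attention_constant_input_closed_form(rng):
    """Constant maps make avg and max descriptors equal: gate = sigma(2 MLP(c))."""
    cfg = AttentionConfig(reduction_ratio=4, mlp_activation="none")
    att = ChannelAttention(8, cfg, rng=rng)
    c = np.arange(8, dtype=np.float32)
    x = np.broadcast_to(c[None, :, None, None], (1, 8, 5, 5)).copy()
    got = att(Tensor(x)).numpy().ravel()
    mlp = (c @ att.w0.weight.data) @ att.w1.weight.data
    np.testing.assert_allclose(got, sigmoid_oracle(2.0 * mlp), atol=1e-5)


def test_spatial_attention_shape_range_and_zero_weights(rng):
    att = SpatialAttention(rng=rng)
    x = np.random.default_rng(0).normal(size=(2, 6, 9, 9))
    out = att(Tensor(x)).numpy()
    assert out.shape == (2, 1, 9, 9)
    assert np.all((out > 0) & (out < 1))
    zero_params(att)
    np.testing.assert_array_equal(att(Tensor(x)).numpy(),
                                  np.full((2, 1, 9, 9), 0.5, np.float32))


def test_spatial_attention_matches_straight_loop_oracle(rng):
    att = SpatialAttention(rng=rng)
    x = np.random.default_rng(11).normal(size=(1, 4, 8, 8)).astype(np.float32)
    ref = spatial_attention_oracle(x, att.conv.weight.data, att.conv.bias.data)
    np.testing.assert_allclose(att(Tensor(x)).numpy(), ref, atol=1e-5)


def test_csam_zero_weights_is_quarter_input(rng):
    csam = CSAM(8, rng=rng)
    zero_params(csam)
    x = np.random.default_rng(0).normal(size=(2, 8, 6, 6)).astype(np.float32)
    np.testing.assert_array_equal(csam(Tensor(x)).numpy(),
                                  np.float32(0.25) * x)


def test_csam_is_channel_then_spatial(rng):
    csam = CSAM(4, rng=rng)
    x = np.random.default_rng(2).normal(size=(1, 4, 7, 7)).astype(np.float32)
    got = csam(Tensor(x)).numpy()
    f1 = csam.channel(Tensor(x)).numpy() * x
    ref = csam.spatial(Tensor(f1)).numpy() * f1
    np.testing.assert_allclose(got, ref, atol=1e-6)
    assert got.shape == x.shape


def test_csam_magnitude_never_exceeds_input(rng):
    csam = CSAM(4, rng=rng)
    x = np.random.default_rng(3).normal(size=(2, 4, 8, 8)).astype(np.float32)
    out = csam(Tensor(x)).numpy()
    assert np.all(np.abs(out) <= np.abs(x) + 1e-7)


# ----------------------------------------------------------------- properties
@pytest.mark.parametrize("shape", [(1, 3, 5, 7), (2, 2, 1, 1), (1, 4, 13, 6)])
def test_blocks_preserve_spatial_dims(shape, rng):
    x = Tensor(np.random.default_rng(0).normal(size=shape))
    c = shape[1]
    for block in (ConvUnit(c, c, rng=rng),
                  MultiDilatedResidualBlock(c, c, rates=(1, 2), rng=rng),
                  ASPP(c, c, rates=(2,), rng=rng),
                  CSAM(c, rng=rng)):
        assert block(x).shape[2:] == shape[2:]
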