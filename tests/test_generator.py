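"""Architecture contracts of the 2.5D VNet generator."""

import numpy as np
import pytest

from liverseg import losses, nn
from liverseg.generator import (
    ArchSpec,
    build_generator,
    count_parameters,
    crp_block,
    downsample_block,
    series_conv_block,
    upsample_block,
)

SMALL = ArchSpec(stage_channels=(4, 8, 8, 8, 8), dropout_rate=0.0)


# --------------------------------------------------------------- conv blocks
def test_series_block_parameter_count_closed_form():
    # 1x3x3 then 3x1x1, both biased: 32·9·32+32 + 32·3·32+32
    assert count_parameters(series_conv_block(32, 32, "series")) == 12352


@pytest.mark.parametrize("cin,cout,expected", [
    (128, 128, 442496),   # Cin·27·Cout + Cout
    (3, 32, 3 * 27 * 32 + 32),
])
def test_full3d_block_parameter_counts(cin, cout, expected):
    assert count_parameters(series_conv_block(cin, cout, "full3d")) == expected


@pytest.mark.parametrize("mode", ["series", "full3d"])
def test_conv_blocks_preserve_spatial_shape(mode, rng):
    block = series_conv_block(4, 6, mode, rng=rng)
    x = nn.Tensor(rng.normal(size=(2, 4, 3, 10, 10)))
    assert block(x).shape == (2, 6, 3, 10, 10)


def test_unknown_kernel_mode_rejected():
    with pytest.raises(ValueError, match="mode"):
        series_conv_block(4, 4, "depthwise")


# ---------------------------------------------------------------- down / up
def test_downsample_halves_in_plane_only(rng):
    block = downsample_block(4, 8, rng=rng)
    x = nn.Tensor(rng.normal(size=(1, 4, 3, 64, 64)))
    assert block(x).shape == (1, 8, 3, 32, 32)
    composed = x
    chain = [downsample_block(4, 4, rng=rng) for _ in range(4)]
    x128 = nn.Tensor(rng.normal(size=(1, 4, 3, 128, 128)))
    for b in chain:
        x128 = b(x128)
    assert x128.shape == (1, 4, 3, 8, 8)


def test_upsample_doubles_and_inverts_downsample_shape(rng):
    up = upsample_block(8, 4, rng=rng)
    x = nn.Tensor(rng.normal(size=(1, 8, 3, 8, 8)))
    assert up(x).shape == (1, 4, 3, 16, 16)
    down = downsample_block(4, 8, rng=rng)
    y = nn.Tensor(rng.normal(size=(1, 4, 3, 10, 10)))
    assert up(down(y)).shape == y.shape


def test_full3d_deconvolution_parameter_count():
    # Cin·27·Cout + Cout for a biased 3x3x3 transposed convolution
    assert count_parameters(upsample_block(256, 512, "full3d")) == 3539456


# ----------------------------------------------------------------- CRP block
def test_crp_preserves_shape_and_channels(rng):
    block = crp_block(8, rng=rng)
    x = nn.Tensor(rng.normal(size=(1, 8, 1, 16, 16)))
    assert block(x).shape == x.shape


def test_crp_with_zeroed_convs_is_identity(rng):
    block = crp_block(4, dropout_rate=0.0, rng=rng)
    for unit in block.units:
        conv = unit.layers[0]
        conv.weight.data[...] = 0.0
        conv.bias.data[...] = 0.0
    x = nn.Tensor(rng.normal(size=(2, 4, 3, 8, 8)))
    assert np.allclose(block(x).data, x.data)


def test_crp_eval_mode_is_deterministic(rng):
    block = crp_block(4, dropout_rate=0.5, rng=rng)
    block.eval()
    x = nn.Tensor(rng.normal(size=(1, 4, 1, 8, 8)))
    assert np.array_equal(block(x).data, block(x).data)


# ------------------------------------------------------------ full generator
def test_generator_output_shape_and_range(rng):
    model = build_generator(SMALL, seed=0)
    x = nn.Tensor(rng.random((2, 3, 64, 64)))
    out = model(x)
    assert out.shape == (2, 1, 64, 64)
    assert np.all(out.data >= 0.0) and np.all(out.data <= 1.0)


def test_default_encoder_channel_plan_reads_back():
    model = build_generator(ArchSpec(), seed=0)
    assert model.encoder_channels == (32, 64, 128, 256, 256)


def test_generator_pads_non_multiple_inplane_sizes(rng):
    model = build_generator(SMALL, seed=0)
    out = model(nn.Tensor(rng.random((1, 3, 36, 44))))
    assert out.shape == (1, 1, 36, 44)


def test_softmax_head_probabilities_sum_to_one(rng):
    model = build_generator(
        ArchSpec(stage_channels=(4, 8, 8, 8, 8), out_channels=2, dropout_rate=0.0),
        seed=0,
    )
    out = model(nn.Tensor(rng.random((1, 3, 32, 32)))).data
    assert out.shape == (1, 2, 32, 32)
    assert np.allclose(out.sum(axis=1), 1.0)


def test_generator_eval_forward_is_deterministic(rng):
    model = build_generator(SMALL, seed=0).eval()
    x = nn.Tensor(rng.random((1, 3, 32, 32)))
    assert np.array_equal(model(x).data, model(x).data)


def test_gradients_of_composite_loss_are_finite_everywhere(rng, small_dataset):
    model = build_generator(SMALL, seed=0)
    stack, mask = small_dataset[3]
    pred = model(nn.Tensor(stack[None]))
    loss = losses.composite_loss(
        pred.reshape(*mask.shape), mask, losses.LossConfig(alpha=0.1))
    model.zero_grad()
    loss.backward()
    for name, p in model.named_parameters():
        assert p.grad is not None, name
        assert np.all(np.isfinite(p.grad)), name


def test_zeroing_skip_feature_changes_decoder_output(rng):
    model = build_generator(SMALL, seed=0).eval()
    x = nn.Tensor(rng.random((1, 3, 32, 32)))
    baseline = model(x).data.copy()
    crp0 = model.crp[0]
    original = crp0.forward
    try:
        crp0.forward = lambda t: original(t * 0.0)
        ablated = model(x).data
    finally:
        crp0.forward = original
    assert not np.allclose(baseline, ablated)


def test_count_parameters_examples():
    assert count_parameters(nn.Conv3d(3, 32, (1, 3, 3))) == 896
    assert count_parameters(nn.Linear(32, 1)) == 33
    assert count_parameters(None) == 0
    assert count_parameters(nn.Sequential()) == 0


def test_arch_spec_validation():
    with pytest.raises(ValueError, match="5 encoder stages"):
        ArchSpec(stage_channels=(32, 64))
    with pytest.raises(ValueError, match="odd"):
        ArchSpec(crp_kernel=4)
    with pytest.raises(ValueError, match="kernel_mode"):
        ArchSpec(kernel_mode="hybrid")
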