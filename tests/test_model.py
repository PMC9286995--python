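"""Architecture contracts: shapes, skip wiring, parameter audits, checkpoints."""

import dataclasses

import numpy as np
import pytest

from lvseg.model import (
    ArchConfig,
    DSConvBNReLU,
    ImprovedResUNet,
    ResidualUnit,
    build_model,
    dsconv_block,
    load_checkpoint,
    normalize_image,
    param_count,
    predict,
    save_checkpoint,
)
from lvseg.nn import autograd as ag
from lvseg.nn.autograd import Tensor

RNG = np.random.default_rng(0)


def small_cfg(**kw) -> ArchConfig:
    base = dict(input_size=32, n_levels=2, base_channels=4, seed=0)
    base.update(kw)
    return ArchConfig(**base)


class TestDSConvBlock:
    def test_s1_s2_half_channel_construction(self):
        blk = dsconv_block(16, 32)
        x = Tensor(RNG.normal(size=(1, 16, 8, 8)).astype(np.float32))
        s1 = blk.block.primary.forward(x)
        s2 = blk.block.cheap.forward(s1)
        assert s1.shape[1] == 16 and s2.shape[1] == 16
        out = blk.forward(x)
        assert out.shape == (1, 32, 8, 8)

    def test_conv_weight_count_formula(self):
        # 9*c1*(c2/2) + 9*(c2/2) vs 9*c1*c2 for the plain twin
        blk = dsconv_block(16, 32)
        assert blk.conv_weight_count() == 9 * 16 * 16 + 9 * 16 == 2448
        assert 9 * 16 * 32 == 4608  # plain 3x3 16->32 twin
        assert blk.conv_weight_count() < 4608

    @pytest.mark.parametrize("c2", [2, 6, 16, 30, 64])
    def test_output_channels_equal_c2(self, c2):
        blk = dsconv_block(3, c2)
        x = Tensor(RNG.normal(size=(1, 3, 4, 4)).astype(np.float32))
        assert blk.forward(x).shape[1] == c2

    def test_odd_c2_rejected_before_weight_allocation(self):
        with pytest.raises(ValueError, match="even"):
            dsconv_block(16, 7)


class TestResidualUnit:
    def test_spatial_dims_preserved(self):
        for ct in ("standard", "depthwise_separable"):
            for ss in (True, False):
                ru = ResidualUnit(3, 8, ct, ss, np.random.default_rng(0))
                x = Tensor(RNG.normal(size=(2, 3, 12, 12)).astype(np.float32))
                assert ru.forward(x).shape == (2, 8, 12, 12)

    def test_zero_residual_weights_reduce_to_bn_relu_identity(self):
        """With zero conv weights and matching channels, out == ReLU(BN(x))."""
        ru = ResidualUnit(4, 4, "standard", True, np.random.default_rng(0))
        ru.block1.conv.weight.data[...] = 0.0
        ru.block2.conv.weight.data[...] = 0.0
        assert ru.proj is None  # identity-compatible channels
        x = Tensor(RNG.normal(size=(3, 4, 6, 6)).astype(np.float32))
        out = ru.forward(x)
        # hand-computed: batch-normalize x with batch stats, then ReLU
        mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
        var = x.data.var(axis=(0, 2, 3), keepdims=True)
        expected = np.maximum((x.data - mu) / np.sqrt(var + 1e-5), 0.0)
        np.testing.assert_allclose(out.data, expected, rtol=1e-4, atol=1e-5)

    def test_short_skip_off_is_plain_two_conv_block(self):
        ru = ResidualUnit(3, 8, "standard", False, np.random.default_rng(0))
        assert ru.proj is None
        # block2 consumes block1's output only (no concatenated input)
        assert ru.block2.conv.weight.shape[1] == 8


class TestBuildModel:
    def test_forward_shape_and_softmax_normalization(self):
        model = build_model(small_cfg())
        x = Tensor(RNG.normal(size=(2, 1, 32, 32)).astype(np.float32))
        model.eval()
        probs = model.forward_probs(x)
        assert probs.shape == (2, 2, 32, 32)
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-5)

    @pytest.mark.parametrize("kw", [
        {},
        {"n_levels": 3, "base_channels": 8, "input_size": 64},
        {"use_medium_skip": False},
        {"use_short_skip": False},
    ])
    def test_improved_has_fewer_params_than_standard_twin(self, kw):
        imp = build_model(small_cfg(conv_type="depthwise_separable", **kw))
        std = build_model(small_cfg(conv_type="standard", **kw))
        assert param_count(imp) < param_count(std)

    def test_medium_skip_param_delta_matches_analytic_formula(self):
        """Concatenative medium skips add the 1x1 conv weights plus the
        induced widening of every downstream residual unit's convs."""
        cfg_on = small_cfg(conv_type="standard", use_medium_skip=True)
        cfg_off = small_cfg(conv_type="standard", use_medium_skip=False)
        delta = param_count(build_model(cfg_on)) - param_count(build_model(cfg_off))
        L, base, in_ch = cfg_on.n_levels, cfg_on.base_channels, cfg_on.in_channels
        e = base  # medium-branch output channels
        medium_w = L * in_ch * base

        def proj_w(c_in, c_out):  # 1x1 projection exists iff channels differ
            return 0 if c_in == c_out else c_in * c_out

        def unit_delta(c_in_off, c_out):
            c_in_on = c_in_off + e
            return (9 * e * c_out            # conv1 widening
                    + 9 * e * c_out          # conv2 widening (concat input)
                    + proj_w(c_in_on, c_out) - proj_w(c_in_off, c_out))

        widen = sum(unit_delta(base * 2 ** (l - 1), base * 2**l)
                    for l in range(1, L))
        widen += unit_delta(base * 2 ** (L - 1), base * 2**L)  # transition
        assert delta == medium_w + widen

    def test_ablation_baseline_is_plain_residual_unet(self):
        cfg = small_cfg(use_medium_skip=False, use_short_skip=False,
                        conv_type="standard")
        model = build_model(cfg)
        assert all(m is None for m in model.medium_convs)
        assert all(not u.use_short_skip for u in model.enc_units + model.dec_units)

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ArchConfig(input_size=100, n_levels=3)

    def test_odd_base_channels_with_separable_rejected(self):
        with pytest.raises(ValueError, match="even"):
            ArchConfig(base_channels=5, conv_type="depthwise_separable")

    def test_param_count_invariant_to_weight_values(self):
        model = build_model(small_cfg())
        n0 = param_count(model)
        for p in model.parameters():
            p.data[...] = RNG.normal(size=p.data.shape)
        assert param_count(model) == n0

    def test_seeded_init_reproducible(self):
        a = build_model(small_cfg(seed=9))
        b = build_model(small_cfg(seed=9))
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)


class TestPredict:
    def test_prob_map_shape(self):
        model = build_model(small_cfg())
        prob, mask = predict(model, RNG.normal(size=(32, 32)))
        assert prob.shape == (32, 32, 2)
        assert mask.shape == (32, 32) and mask.dtype == bool

    def test_shape_mismatch_reports_both_shapes(self):
        model = build_model(small_cfg())
        with pytest.raises(ValueError, match=r"\(40, 40\).*\(32, 32\)"):
            predict(model, np.zeros((40, 40)))

    def test_uniform_scores_tie_break_to_background(self):
        model = build_model(small_cfg())
        for p in model.parameters():
            p.data[...] = 0.0  # all-zero net -> identical class scores
        _, mask = predict(model, RNG.normal(size=(32, 32)))
        assert not mask.any()

    def test_largest_component_postprocessing(self):
        model = build_model(small_cfg(seed=3))
        _, mask = predict(model, RNG.normal(size=(32, 32)))
        if mask.any():
            from skimage.measure import label

            assert label(mask, connectivity=1).max() == 1


def test_checkpoint_roundtrip(tmp_path):
    model = build_model(small_cfg(seed=4))
    # push some BN state away from init so buffers are exercised
    x = Tensor(RNG.normal(size=(2, 1, 32, 32)).astype(np.float32))
    model.train()
    model.forward(x)
    save_checkpoint(model, tmp_path / "ckpt")
    loaded = load_checkpoint(tmp_path / "ckpt")
    assert loaded.config == model.config
    img = RNG.normal(size=(32, 32))
    np.testing.assert_array_equal(predict(model, img)[0], predict(loaded, img)[0])


def test_normalize_image_zero_mean_unit_sd():
    img = RNG.normal(50, 7, size=(16, 16))
    z = normalize_image(img)
    assert abs(z.mean()) < 1e-5 and abs(z.std() - 1) < 1e-4
    assert not normalize_image(np.full((4, 4), 3.0)).any()
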