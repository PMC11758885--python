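"""Unit and property tests for the architecture: channel plumbing, unit
structures, attention modules, shape contracts and parameter counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lwheatnet import nn
from lwheatnet.model_core import (AttentionConfig, BasicUnit, ConvSpec, CoreLayer,
                                  DownsamplingUnit, ECAAttention, LWheatNet,
                                  MixedAttention, ModelConfig, TPSAAttention,
                                  build_model, canonical_variant, channel_shuffle,
                                  channel_split, count_parameters,
                                  depthwise_separable_conv, eca_kernel_size,
                                  format_param_count, load_checkpoint,
                                  save_checkpoint)


class TestChannelSplit:
    def test_halves_leading_and_trailing_channels(self, rng):
        x = rng.standard_normal((48, 56, 56)).astype(np.float32)
        a, b = channel_split(x)
        assert a.shape == b.shape == (24, 56, 56)
        np.testing.assert_array_equal(a, x[:24])
        np.testing.assert_array_equal(b, x[24:])

    def test_order_on_named_channels(self):
        x = np.arange(4, dtype=np.float32).reshape(4, 1, 1)  # channels a,b,c,d
        a, b = channel_split(x)
        np.testing.assert_array_equal(a.ravel(), [0, 1])
        np.testing.assert_array_equal(b.ravel(), [2, 3])

    def test_odd_channel_count_rejected(self, rng):
        with pytest.raises(ValueError, match="even"):
            channel_split(rng.standard_normal((47, 8, 8)))


class TestChannelShuffle:
    def test_group_transpose_on_four_channels(self):
        x = np.arange(4, dtype=np.float32).reshape(4, 1, 1)
        y = channel_shuffle(x, 2)
        np.testing.assert_array_equal(y.ravel(), [0, 2, 1, 3])  # [a,c,b,d]

    def test_single_group_is_identity(self, rng):
        x = rng.standard_normal((6, 3, 3))
        np.testing.assert_array_equal(channel_shuffle(x, 1), x)

    def test_double_shuffle_two_groups_four_channels_is_identity(self, rng):
        # derived by composing the permutation [0,2,1,3] with itself
        x = rng.standard_normal((4, 2, 2))
        np.testing.assert_array_equal(channel_shuffle(channel_shuffle(x, 2), 2), x)

    @pytest.mark.parametrize("channels,groups", [(8, 2), (12, 3), (16, 4), (16, 2)])
    def test_is_pure_permutation_and_invertible(self, rng, channels, groups):
        x = rng.standard_normal((channels, 2, 2))
        y = channel_shuffle(x, groups)
        # channel contents are preserved as a multiset
        np.testing.assert_allclose(np.sort(x, axis=0), np.sort(y, axis=0))
        # shuffle by C/groups inverts
        np.testing.assert_array_equal(channel_shuffle(y, channels // groups), x)

    def test_non_divisible_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            channel_shuffle(rng.standard_normal((6, 2, 2)), 4)


class TestDepthwiseSeparableConv:
    def test_same_padding_preserves_shape_at_stride_1(self, rng):
        spec = ConvSpec(kernel=3, in_channels=24, out_channels=24, depthwise=True)
        x = rng.standard_normal((24, 56, 56)).astype(np.float32)
        assert depthwise_separable_conv(x, spec).shape == (24, 56, 56)

    def test_stride_2_halves_spatial_dims(self, rng):
        spec = ConvSpec(kernel=3, in_channels=24, out_channels=24, stride=2,
                        depthwise=True)
        x = rng.standard_normal((24, 56, 56)).astype(np.float32)
        assert depthwise_separable_conv(x, spec).shape == (24, 28, 28)

    def test_depthwise_weight_count(self):
        # 3x3 depthwise on 24 channels, no bias: 9 * 24 = 216 weights
        dw = nn.DepthwiseConv2d(24, 3)
        assert dw.weight.size == 216

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            ConvSpec(kernel=4, in_channels=8, out_channels=8)

    def test_depthwise_requires_matching_channels(self):
        with pytest.raises(ValueError, match="depthwise"):
            ConvSpec(kernel=3, in_channels=8, out_channels=16, depthwise=True)


class TestUnits:
    def test_basic_unit_preserves_shape(self, rng):
        unit = BasicUnit(116, rng=rng)
        x = rng.standard_normal((2, 116, 28, 28)).astype(np.float32)
        assert unit.forward(x).shape == (2, 116, 28, 28)

    def test_basic_unit_left_half_untouched_before_shuffle(self, rng):
        # undo the final shuffle: the left group must be the input's
        # first width/2 channels exactly
        width = 16
        unit = BasicUnit(width, rng=rng)
        x = rng.standard_normal((1, width, 8, 8)).astype(np.float32)
        y = unit.forward(x)
        pre_shuffle = channel_shuffle(y, width // 2)  # invert groups=2 shuffle
        np.testing.assert_array_equal(pre_shuffle[:, :width // 2], x[:, :width // 2])

    def test_basic_unit_shuffle_is_group_transpose_of_indices(self):
        # output channel i holds pre-concat channel perm[i], where perm is the
        # reshape-(2, w/2)-transpose permutation of 0..width-1
        width = 8
        perm = np.arange(width).reshape(2, width // 2).T.ravel()
        x = np.arange(width, dtype=np.float32).reshape(1, width, 1, 1)
        np.testing.assert_array_equal(channel_shuffle(x, 2).ravel(), perm)

    def test_basic_unit_width_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="channels"):
            BasicUnit(16, rng=rng).forward(
                rng.standard_normal((1, 8, 4, 4)).astype(np.float32))

    @pytest.mark.parametrize("in_c,out_w,hw,expected", [
        (24, 116, 56, (28, 116)),
        (116, 232, 28, (14, 232)),
    ])
    def test_downsampling_unit_shape(self, rng, in_c, out_w, hw, expected):
        unit = DownsamplingUnit(in_c, out_w, rng=rng)
        x = rng.standard_normal((1, in_c, hw, hw)).astype(np.float32)
        y = unit.forward(x)
        assert y.shape == (1, out_w, expected[0], expected[0])

    def test_downsampling_branches_contribute_half_each(self, rng):
        unit = DownsamplingUnit(24, 116, rng=rng)
        x = rng.standard_normal((1, 24, 8, 8)).astype(np.float32)
        left = unit.left.forward(x)
        right = unit.right.forward(x)
        assert left.shape[1] == right.shape[1] == 58

    def test_odd_out_width_rejected(self, rng):
        with pytest.raises(ValueError, match="even"):
            DownsamplingUnit(24, 117, rng=rng)

    def test_core_layer_shape_and_unit_count(self, rng):
        layer = CoreLayer(24, 116, repeats=3, rng=rng)
        assert len(layer.layers) == 4  # 1 downsampling + 3 basic
        x = rng.standard_normal((1, 24, 56, 56)).astype(np.float32)
        assert layer.forward(x).shape == (1, 116, 28, 28)

    def test_core_layer_repeats_one_executes_two_units(self, rng):
        assert len(CoreLayer(8, 16, repeats=1, rng=rng).layers) == 2

    def test_core_layer_params_additive_over_units(self, rng):
        layer = CoreLayer(24, 116, repeats=3, rng=rng)
        total = sum(p.size for p in layer.parameters())
        per_unit = [sum(p.size for p in u.parameters()) for u in layer.layers]
        assert total == sum(per_unit)


class TestEcaKernelSize:
    @pytest.mark.parametrize("channels,expected", [
        (1024, 5),  # 10/2 + 1/2 = 5.5 -> nearest odd 5
        (24, 3),    # log2(24)/2 + 0.5 ~ 2.79 -> 3
        (2, 1),     # 0.5 + 0.5 = 1, already odd
        (232, 5),
        (464, 5),
    ])
    def test_known_values(self, channels, expected):
        assert eca_kernel_size(channels) == expected

    def test_odd_and_monotone_over_full_range(self):
        ks = [eca_kernel_size(c) for c in range(1, 4097)]
        assert all(k >= 1 and k % 2 == 1 for k in ks)
        assert all(b >= a for a, b in zip(ks, ks[1:]))

    def test_invalid_channels_rejected(self):
        with pytest.raises(ValueError):
            eca_kernel_size(0)


class TestAttention:
    @pytest.mark.parametrize("cls,kwargs", [
        (ECAAttention, {}),
        (TPSAAttention, {}),
        (TPSAAttention, {"spatial": True}),
    ])
    def test_gating_shape_weights_and_zero_input(self, rng, cls, kwargs):
        mod = cls(32, **kwargs)
        x = rng.standard_normal((2, 32, 8, 8)).astype(np.float32)
        y = mod.forward(x)
        assert y.shape == x.shape
        # sigmoid gate: |out| <= |in| elementwise, zeros map to zeros
        assert np.all(np.abs(y) <= np.abs(x) + 1e-7)
        assert np.all(mod.forward(np.zeros_like(x)) == 0)

    def test_tpsa_parameter_count_at_464_channels(self):
        # 464*29+29 + 9*29^2+29 + 25*29^2+29 + 29*464+464 = 56,057
        tpsa = TPSAAttention(464, reduction=16)
        assert sum(p.size for p in tpsa.parameters()) == 56057

    def test_tpsa_reduction_clamps_to_one_channel(self):
        tpsa = TPSAAttention(8, reduction=16)
        assert tpsa.reduced == 1

    def test_mam_backbone_variant_is_identity(self, rng):
        mod = MixedAttention(16, AttentionConfig(), "backbone")
        x = rng.standard_normal((1, 16, 4, 4)).astype(np.float32)
        np.testing.assert_array_equal(mod.forward(x), x)

    def test_mam_full_variant_sums_branches_and_gates_zero(self, rng):
        mod = MixedAttention(16, AttentionConfig(), "backbone+tpsa+eca")
        x = rng.standard_normal((2, 16, 4, 4)).astype(np.float32)
        y = mod.forward(x)
        assert y.shape == x.shape
        np.testing.assert_allclose(
            y, mod.eca.forward(x) + mod.tpsa.forward(x), rtol=1e-6)
        assert np.all(mod.forward(np.zeros_like(x)) == 0)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            canonical_variant("resnet50")


class TestBuildModel:
    def test_stem_and_pool_shape_walk(self, rng):
        model = build_model(ModelConfig(variant="backbone"))
        x = rng.standard_normal((1, 3, 224, 224)).astype(np.float32)
        after_stem = model.stem.forward(x)
        assert after_stem.shape == (1, 24, 112, 112)
        after_pool = model.pool.forward(after_stem)
        assert after_pool.shape == (1, 24, 56, 56)

    def test_logits_length_and_softmax_normalisation(self, rng):
        model = build_model(ModelConfig(variant="backbone+tpsa+eca"))
        x = rng.standard_normal((2, 3, 224, 224)).astype(np.float32)
        probs = model.predict_proba(x)
        assert probs.shape == (2, 5)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    @settings(max_examples=12, deadline=None)
    @given(hw=st.integers(8, 64), c=st.sampled_from([8, 16, 24, 48]))
    def test_unit_shape_contracts_randomised(self, hw, c):
        rng = np.random.default_rng(hw * 100 + c)
        x = rng.standard_normal((1, c, hw, hw)).astype(np.float32)
        assert BasicUnit(c, rng=rng).forward(x).shape == x.shape
        y = DownsamplingUnit(c, 2 * c, rng=rng).forward(x)
        assert y.shape == (1, 2 * c, (hw + 1) // 2, (hw + 1) // 2)

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(stage_channels=(115, 232, 464))
        with pytest.raises(ValueError):
            ModelConfig(num_classes=1)
        with pytest.raises(ValueError):
            ModelConfig(dropout_p=1.0)


class TestCountParameters:
    def test_stem_block_count(self):
        # 3x3 conv 3->24 no bias (648) + BN scale/shift (48) = 696
        model = build_model(ModelConfig(variant="backbone"))
        assert count_parameters(model).per_block["stem"] == 696

    def test_total_matches_brute_force_enumeration(self):
        model = build_model(ModelConfig(variant="backbone+tpsa+eca"))
        counts = count_parameters(model)
        brute = sum(p.data.size for _, p in model.named_parameters())
        assert counts.total == brute
        assert counts.total == sum(counts.per_block.values())

    def test_variant_nesting_and_eca_increment(self):
        totals = {}
        for v in ("backbone", "backbone+tpsa", "backbone+tpsa+eca"):
            totals[v] = count_parameters(build_model(ModelConfig(variant=v))).total
        assert totals["backbone"] < totals["backbone+tpsa"] <= totals["backbone+tpsa+eca"]
        assert totals["backbone+tpsa+eca"] - totals["backbone+tpsa"] < 100

    def test_format(self):
        assert format_param_count(1258729) == "1.26M"


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, rng, tmp_path):
        cfg = ModelConfig(input_size=32, stage_channels=(8, 16, 32),
                          stage_repeats=(1, 1, 1), head_channels=16,
                          num_classes=3, variant="backbone+tpsa+eca")
        model = build_model(cfg)
        x = rng.standard_normal((2, 3, 32, 32)).astype(np.float32)
        before = model.predict_proba(x)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        np.testing.assert_array_equal(restored.predict_proba(x), before)
        assert restored.config == cfg
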