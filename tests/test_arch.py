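"""Architecture construction, parameter accounting, and the separable
convolution cost model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svncnet.arch import (ArchConfig, CostSpec, build_svnc_net,
                          cost_reduction_ratio, count_parameters,
                          model_summary, round_millions_1dp,
                          separable_conv_cost, standard_conv_cost)
from svncnet.nn.ops import DWConv2d, PWConv


class TestParameterBudget:
    def test_reference_model_is_one_million_at_one_decimal(self):
        summary = count_parameters(build_svnc_net(ArchConfig()))
        assert 950_000 <= summary.total_params <= 1_049_999
        assert summary.params_millions_1dp == 1.0
        assert summary.nonzero_params <= summary.total_params

    def test_count_independent_of_input_size_and_padding(self):
        ref = count_parameters(build_svnc_net(ArchConfig())).total_params
        for cfg in (ArchConfig(input_size=256),
                    ArchConfig(padding_mode="valid_stage4")):
            assert count_parameters(build_svnc_net(cfg)).total_params == ref

    def test_pointwise_head_and_separable_block_counts(self):
        head = PWConv("h", "input", 32, 1, bias=True)
        assert sum(p.size for p in head.parameters()) == 33
        dw = DWConv2d("d", "input", 32)
        pw = PWConv("p", "input", 32, 64)
        assert dw.W.size + pw.W.size == 288 + 2048 == 2336

    def test_round_half_up(self):
        assert round_millions_1dp(950_000) == 1.0
        assert round_millions_1dp(949_999) == 0.9
        assert round_millions_1dp(1_049_999) == 1.0


class TestForwardContract:
    def test_output_matches_input_shape_and_range(self, tiny_arch):
        model = build_svnc_net(tiny_arch, seed=0)
        x = np.random.default_rng(1).random((2, 1, 64, 64), dtype=np.float32)
        y = model(x)
        assert y.shape == (2, 1, 64, 64)
        assert y.min() >= 0.0 and y.max() <= 1.0

    def test_default_width_forward_at_divisible_size(self):
        # spatial contract holds for any side divisible by 2^4
        model = build_svnc_net(ArchConfig(input_size=128), seed=0)
        x = np.random.default_rng(2).random((1, 1, 128, 128), dtype=np.float32)
        y = model(x)
        assert y.shape == (1, 1, 128, 128)
        assert np.all((y >= 0) & (y <= 1))

    def test_eval_forward_is_deterministic(self, tiny_arch):
        model = build_svnc_net(tiny_arch, seed=3)
        x = np.random.default_rng(4).random((1, 1, 64, 64), dtype=np.float32)
        assert np.array_equal(model(x), model(x))

    def test_valid_stage4_forward_shape(self):
        cfg = ArchConfig(input_size=128, stage_widths=(4, 8, 16, 32),
                         bottleneck_width=64, padding_mode="valid_stage4")
        model = build_svnc_net(cfg, seed=0)
        x = np.zeros((1, 1, 128, 128), dtype=np.float32)
        assert model(x).shape == (1, 1, 128, 128)


class TestSummary:
    def test_bottleneck_spatial_size_by_padding_mode(self):
        same = build_svnc_net(ArchConfig())
        hw = same.graph.infer_hw((512, 512))
        assert hw["bottleneckb.pw_relu"] == (32, 32)
        valid = build_svnc_net(ArchConfig(padding_mode="valid_stage4"))
        assert valid.graph.infer_hw((512, 512))["bottleneckb.pw_relu"] == (30, 30)

    def test_decoder_stage_output_sides(self):
        model = build_svnc_net(ArchConfig())
        hw = model.graph.infer_hw((512, 512))
        for stage, side in ((4, 64), (3, 128), (2, 256), (1, 512)):
            assert hw[f"dec{stage}b.pw_relu" if stage >= 2 else f"dec{stage}b.relu"] == (side, side)

    def test_layer_table_stable_across_builds(self, tiny_arch):
        t1 = model_summary(build_svnc_net(tiny_arch, seed=0)).layer_table
        t2 = model_summary(build_svnc_net(tiny_arch, seed=5)).layer_table
        assert [r["name"] for r in t1] == [r["name"] for r in t2]
        assert len(t1) > 50


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(input_size=100),                       # not divisible by 16
        dict(stage_widths=(32, 64, 64, 256)),       # not strictly increasing
        dict(out_channels=0),
        dict(padding_mode="reflect"),
        dict(bottleneck_width=128),                 # not wider than last stage
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ArchConfig(**kwargs)


class TestCostModel:
    def test_worked_standard_cost(self):
        assert standard_conv_cost(CostSpec(3, 32, 64, 256)) == 1_207_959_552

    def test_worked_separable_cost(self):
        assert separable_conv_cost(CostSpec(3, 32, 64, 256)) == 18_874_368 + 134_217_728

    def test_pointwise_special_case(self):
        s = CostSpec(1, 7, 11, 13)
        assert standard_conv_cost(s) == 7 * 11 * 13 ** 2
        assert separable_conv_cost(s) == 7 * 13 ** 2 + 7 * 11 * 13 ** 2

    def test_reduction_ratio_values(self):
        assert cost_reduction_ratio(3, 64) == pytest.approx(1 / 64 + 1 / 9, abs=0)
        assert cost_reduction_ratio(1, 1) == 2.0

    @pytest.mark.parametrize("bad", [(0, 4), (3, 0)])
    def test_cost_domain_errors(self, bad):
        with pytest.raises(ValueError):
            cost_reduction_ratio(*bad)

    @pytest.mark.parametrize("spec", [(0, 1, 1, 1), (3, -2, 4, 8), (3, 2, 4, 0)])
    def test_cost_spec_requires_positive_integers(self, spec):
        with pytest.raises(ValueError):
            CostSpec(*spec)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(Dk=st.integers(1, 9), M=st.integers(1, 512), N=st.integers(1, 512),
           Df=st.integers(1, 256))
    def test_ratio_identity_over_random_specs(self, Dk, M, N, Df):
        """separable/standard == 1/N + 1/Dk^2, independent of M and Df."""
        s = CostSpec(Dk, M, N, Df)
        ratio = separable_conv_cost(s) / standard_conv_cost(s)
        assert ratio == pytest.approx(cost_reduction_ratio(Dk, N), abs=1e-12)
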