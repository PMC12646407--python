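"""Magnitude weight pruning, structural filter pruning, and int8
post-training quantization."""

import numpy as np
import pytest

from svncnet.arch import ArchConfig, build_svnc_net
from svncnet.compression import (PruneConfig, QuantConfig,
                                 _prunable_weights, compression_report,
                                 filter_prune, fold_batchnorm,
                                 magnitude_weight_prune, quantize_int8)
from svncnet.nn import BatchNorm2d, Conv2d, Graph, ReLU, Sigmoid


@pytest.fixture(scope="module")
def tiny_model(tiny_arch):
    return build_svnc_net(tiny_arch, seed=1)


def _nonzero(model):
    return sum(p.nonzero for p in model.parameters())


class TestMagnitudeWeightPrune:
    def test_fraction_zero_is_identity(self, tiny_model):
        pruned = magnitude_weight_prune(tiny_model, PruneConfig(weight_fraction=0.0))
        assert _nonzero(pruned) == _nonzero(tiny_model)
        for a, b in zip(pruned.parameters(), tiny_model.parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_toy_layer_smallest_three_zeroed(self):
        g = Graph(1)
        conv = Conv2d("c", "input", 1, 10, k=1)
        conv.W.data = np.arange(1, 11, dtype=np.float32).reshape(10, 1, 1, 1)
        g.add(conv)
        pruned = magnitude_weight_prune(g, PruneConfig(weight_fraction=0.3))
        w = pruned.by_name["c"].W.data.ravel()
        assert sorted(w[w != 0].tolist()) == [4, 5, 6, 7, 8, 9, 10]

    def test_exact_count_arithmetic(self, tiny_model):
        P = sum(p.size for p in _prunable_weights(tiny_model.graph))
        total = sum(p.size for p in tiny_model.parameters())
        for f in (0.1, 0.15, 0.37):
            pruned = magnitude_weight_prune(tiny_model, PruneConfig(weight_fraction=f))
            assert _nonzero(pruned) == total - int(np.floor(f * P))

    def test_batch_norm_and_bias_untouched(self, tiny_model):
        pruned = magnitude_weight_prune(tiny_model, PruneConfig(weight_fraction=0.5))
        for a, b in zip(pruned.graph.nodes, tiny_model.graph.nodes):
            if isinstance(a, BatchNorm2d):
                np.testing.assert_array_equal(a.gamma.data, b.gamma.data)
                np.testing.assert_array_equal(a.beta.data, b.beta.data)

    def test_idempotent_and_monotone(self, tiny_model):
        once = magnitude_weight_prune(tiny_model, PruneConfig(weight_fraction=0.2))
        twice = magnitude_weight_prune(once, PruneConfig(weight_fraction=0.2))
        assert _nonzero(once) == _nonzero(twice)
        counts = [_nonzero(magnitude_weight_prune(tiny_model,
                                                  PruneConfig(weight_fraction=f)))
                  for f in (0.0, 0.1, 0.3, 0.6)]
        assert counts == sorted(counts, reverse=True)

    def test_fraction_one_rejected(self):
        with pytest.raises(ValueError):
            PruneConfig(weight_fraction=1.0)

    def test_reference_model_prunes_to_point_nine_million(self):
        model = build_svnc_net(ArchConfig(), seed=0)
        pruned = magnitude_weight_prune(model, PruneConfig(weight_fraction=0.15))
        report = compression_report(pruned, latency_reps=1, input_hw=(64, 64))
        assert report.params_millions_1dp == 0.9


def _two_layer_net(filters=8):
    g = Graph(3)
    rng = np.random.default_rng(0)
    g.add(Conv2d("c1", "input", 3, filters, k=3, rng=rng))
    g.add(ReLU("r1", ["c1"]))
    g.add(Conv2d("c2", "r1", filters, filters, k=3, rng=rng))
    g.add(Sigmoid("s", ["c2"]))
    return g


class TestFilterPrune:
    def test_fraction_zero_preserves_architecture(self, tiny_model):
        pruned = filter_prune(tiny_model, PruneConfig(filter_fraction=0.0))
        assert sum(p.size for p in pruned.parameters()) == sum(
            p.size for p in tiny_model.parameters())

    def test_toy_two_layer_bookkeeping(self):
        g = _two_layer_net(8)
        pruned = filter_prune(g, PruneConfig(filter_fraction=0.25))
        c1, c2 = pruned.by_name["c1"], pruned.by_name["c2"]
        # 2 of 8 filters removed from layer 1; matching inputs from layer 2
        assert c1.W.data.shape == (6, 3, 3, 3)
        assert c2.W.data.shape == (8, 6, 3, 3)
        expected = 6 * 3 * 9 + 8 * 6 * 9
        assert sum(p.size for p in pruned.parameters()) == expected

    def test_smallest_l1_filters_removed(self):
        g = _two_layer_net(8)
        c1 = g.by_name["c1"]
        norms = np.abs(c1.W.data).reshape(8, -1).sum(axis=1)
        drop = set(np.argsort(norms)[:2].tolist())
        pruned = filter_prune(g, PruneConfig(filter_fraction=0.25))
        kept_norms = np.abs(pruned.by_name["c1"].W.data).reshape(6, -1).sum(axis=1)
        expected = sorted(n for i, n in enumerate(norms) if i not in drop)
        np.testing.assert_allclose(sorted(kept_norms), expected, rtol=1e-6)

    def test_skip_connections_survive_forward(self, tiny_model):
        pruned = filter_prune(tiny_model, PruneConfig(filter_fraction=0.20,
                                                      strategy="W+F"))
        x = np.random.default_rng(3).random((2, 1, 64, 64), dtype=np.float32)
        y = pruned.graph.forward(x)
        assert y.shape == (2, 1, 64, 64)
        assert sum(p.size for p in pruned.parameters()) < sum(
            p.size for p in tiny_model.parameters())


class TestQuantization:
    def test_dequantized_within_half_step(self, tiny_model):
        x = [np.random.default_rng(0).random((1, 1, 64, 64), dtype=np.float32)]
        q = quantize_int8(tiny_model, x)
        folded = fold_batchnorm(tiny_model)
        originals = {p.name: p.data for p in folded.parameters()}
        for name, (qa, scale) in q.qweights.items():
            deq = qa.astype(np.float32) * scale
            assert np.abs(originals[name] - deq).max() <= scale / 2 + 1e-7

    def test_weight_payload_quarter_of_float(self, tiny_model):
        x = [np.zeros((1, 1, 64, 64), dtype=np.float32)]
        q = quantize_int8(tiny_model, x)
        assert q.weight_payload_bytes() <= 0.26 * q.float_weight_payload_bytes()

    def test_empty_calibration_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            quantize_int8(tiny_model, [])

    def test_bn_folding_preserves_eval_forward(self, smoke):
        # on a trained model (nontrivial running stats)
        model = smoke["model"]
        folded = fold_batchnorm(model)
        x = np.stack([r.image for r in smoke["records"][:4]]).astype(np.float32)[:, None]
        np.testing.assert_allclose(folded.graph.forward(x),
                                   model.predict_proba(x), atol=1e-4)

    def test_quantized_iou_drop_small_on_phantoms(self, smoke):
        from svncnet.metrics import MaskPair, binarize, iou
        model = smoke["model"]
        records = smoke["records"]
        calib = [np.stack([r.image for r in records[:8]]).astype(np.float32)[:, None]]
        q = quantize_int8(model, calib)
        held = records[::5]
        x = np.stack([r.image for r in held]).astype(np.float32)[:, None]
        base = model.predict_proba(x)
        quant = q.predict_proba(x)
        base_iou = np.mean([iou(MaskPair(binarize(base[i, 0]), held[i].mask))
                            for i in range(len(held))])
        quant_iou = np.mean([iou(MaskPair(binarize(quant[i, 0]), held[i].mask))
                             for i in range(len(held))])
        assert base_iou - quant_iou < 0.05

    def test_bit_width_fixed(self):
        with pytest.raises(ValueError):
            QuantConfig(bit_width=4)


class TestCompressionReport:
    def test_unpruned_reference_reports_one_million(self):
        model = build_svnc_net(ArchConfig(), seed=0)
        rep = compression_report(model, latency_reps=1, input_hw=(64, 64))
        assert rep.params_millions_1dp == 1.0
        assert rep.serialized_bytes > 0
        assert rep.nonzero_params <= rep.total_params

    def test_ten_percent_reduction_in_reported_figures(self):
        model = build_svnc_net(ArchConfig(), seed=0)
        pruned = magnitude_weight_prune(model, PruneConfig(weight_fraction=0.15))
        a = compression_report(model, latency_reps=1, input_hw=(64, 64))
        b = compression_report(pruned, latency_reps=1, input_hw=(64, 64))
        reduction = (a.params_millions_1dp - b.params_millions_1dp) / a.params_millions_1dp
        assert reduction == pytest.approx(0.10, abs=1e-12)

    def test_fraction_zero_report_matches_original(self, tiny_model):
        pruned = magnitude_weight_prune(tiny_model, PruneConfig(weight_fraction=0.0))
        a = compression_report(tiny_model, latency_reps=1)
        b = compression_report(pruned, latency_reps=1)
        assert (a.nonzero_params, a.total_params) == (b.nonzero_params, b.total_params)
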