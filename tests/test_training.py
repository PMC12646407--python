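"""Training loop, volume inference, round evaluation, checkpoints, CLI."""

import json

import numpy as np
import pandas as pd
import pytest

from svncnet.arch import ArchConfig, build_svnc_net
from svncnet.checkpoint import load_checkpoint, save_checkpoint
from svncnet.metrics import MaskPair, dsc_from_iou, iou
from svncnet.phantom import PhantomConfig, phantom_dataset
from svncnet.pipeline import Volume, make_folds
from svncnet.schedule import ScheduleConfig
from svncnet.training import (RunConfig, evaluate_round, predict_volume,
                              train_model)
from conftest import PHANTOM_64


class TestTrainingLoop:
    def test_overfit_smoke_reaches_target_dice(self, smoke):
        assert smoke["train_dice"] >= 0.9

    def test_learning_rate_logged_at_restarts(self, smoke):
        hist = smoke["log"].history
        assert hist.loc[0, "lr"] == pytest.approx(1e-3)
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]

    def test_full_plan_restart_epochs(self, tiny_arch):
        run = RunConfig(arch=tiny_arch, schedule=ScheduleConfig(), epochs=50)
        from svncnet.schedule import schedule_over_training
        lrs = schedule_over_training(run.schedule)
        for e in (0, 10, 30):
            assert lrs[e] == pytest.approx(1e-3)

    def test_same_seed_reproduces_final_loss(self, tiny_arch):
        cfg = PhantomConfig(n_volumes=2, seed=21, **PHANTOM_64)
        records, _ = phantom_dataset(cfg, target_size=64)
        run = RunConfig(arch=tiny_arch, schedule=ScheduleConfig(cycle_lengths=(2,)),
                        epochs=2, batch_size=8, seed=13)
        finals = []
        for _ in range(2):
            model = build_svnc_net(tiny_arch, seed=run.seed)
            log = train_model(model, records, None, run)
            finals.append(log.final_train_loss)
        assert finals[0] == pytest.approx(finals[1], abs=1e-9)

    def test_empty_training_split_rejected(self, tiny_arch):
        run = RunConfig(arch=tiny_arch, schedule=ScheduleConfig(cycle_lengths=(1,)),
                        epochs=1)
        with pytest.raises(ValueError):
            train_model(build_svnc_net(tiny_arch), [], None, run)

    def test_epoch_schedule_mismatch_rejected(self, tiny_arch):
        with pytest.raises(ValueError):
            RunConfig(arch=tiny_arch, schedule=ScheduleConfig(), epochs=10)


class TestPredictVolume:
    def test_held_out_volume_iou(self, smoke):
        vals = []
        for vol in smoke["held_out"]:
            pred = predict_volume(smoke["model"], vol, target_size=64)
            assert pred.shape == vol.image.shape
            assert set(np.unique(pred)) <= {0, 1}
            vals.append(iou(MaskPair(pred, vol.mask)))
        assert min(vals) >= 0.8

    def test_background_only_volume_near_empty(self, smoke):
        rng = np.random.default_rng(0)
        img = (0.2 + 0.03 * rng.normal(size=(12, 64, 64))).astype(np.float32)
        vol = Volume(image=img, identifier="flat")
        pred = predict_volume(smoke["model"], vol, target_size=64, normalize=False)
        assert pred.mean() < 0.01


class TestEvaluateRound:
    def test_metrics_on_test_fold_only(self, smoke):
        records = smoke["records"]
        fa = make_folds(records, seed=3)
        report = evaluate_round(smoke["model"], records, fa, "E1")
        n_test = len(fa.indices_of("F9"))
        assert len(report.per_item) == n_test
        assert 0.0 <= report.iou <= 1.0

    def test_dsc_column_consistent_with_iou_identity(self, smoke):
        records = smoke["records"]
        fa = make_folds(records, seed=3)
        report = evaluate_round(smoke["model"], records, fa, "E2")
        for _, row in report.per_item.iterrows():
            assert row["dsc"] == pytest.approx(dsc_from_iou(row["iou"]), abs=1e-9)

    def test_unknown_round_rejected(self, smoke):
        fa = make_folds(smoke["records"], seed=3)
        with pytest.raises(ValueError):
            evaluate_round(smoke["model"], smoke["records"], fa, "E4")


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, smoke, tmp_path):
        model = smoke["model"]
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path, extra={"seed": 7})
        loaded, extra = load_checkpoint(path)
        assert extra == {"seed": 7}
        x = np.stack([r.image for r in smoke["records"][:2]]).astype(np.float32)[:, None]
        np.testing.assert_allclose(loaded.predict_proba(x),
                                   model.predict_proba(x), atol=1e-6)


class TestCli:
    def test_end_to_end_phantom_train_predict_evaluate(self, tmp_path):
        import yaml
        from svncnet.cli import main

        cfg = {
            "arch": {"input_size": 32, "stage_widths": [4, 8, 16, 32],
                     "bottleneck_width": 64},
            "schedule": {"cycle_lengths": [2]},
            "train": {"epochs": 2, "batch_size": 8, "target_size": 32},
            "phantom": {"shape": [12, 32, 32], "n_volumes": 6,
                        "semi_axes_range": [[2.5, 4.0], [6.0, 10.0], [6.0, 10.0]],
                        "center_jitter": 2.0},
        }
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        out = tmp_path / "out"

        base = ["--config", str(cfg_path), "--seed", "5", "--out", str(out)]
        assert main(base + ["phantom"]) == 0
        niftis = sorted(out.glob("*_image.nii.gz"))
        assert len(niftis) == 6

        assert main(base + ["prepare"]) == 0
        manifest = pd.read_csv(out / "manifest.csv")
        assert {"volume_id", "z_index", "fold"} <= set(manifest.columns)

        assert main(base + ["train", "--round", "E1"]) == 0
        assert (out / "checkpoint.npz").exists()

        assert main(base + ["predict", str(out / "checkpoint.npz"),
                            str(niftis[0])]) == 0

        assert main(base + ["evaluate", str(out / "checkpoint.npz"),
                            "--round", "E1"]) == 0
        metrics = json.loads((out / "metrics_E1.json").read_text())
        assert {"iou", "miou", "dsc"} <= set(metrics["aggregate"])

        assert main(base + ["compress", str(out / "checkpoint.npz")]) == 0
        comp = json.loads((out / "compression.json").read_text())
        assert {"original", "pruned", "quantized"} <= set(comp)
        assert comp["pruned"]["nonzero_params"] < comp["original"]["nonzero_params"]
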