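"""Training pipeline: padding, optimization, checkpoints, evaluation, prediction."""

import numpy as np
import pytest
from PIL import Image

from mhanet import ModelConfig, assemble_mhanet, load_checkpoint, save_checkpoint
from mhanet.data import crop_back, pad_to_stride, split_indices, to_batch
from mhanet.train import TrainConfig, evaluate, mean_val_dice, predict, train


class TestPadding:
    def test_divisible_input_unchanged(self):
        img = np.zeros((800, 800, 3), dtype=np.float32)
        padded, rec = pad_to_stride(img)
        assert padded.shape == img.shape and (rec.height, rec.width) == (800, 800)

    def test_drive_size_pads_to_next_multiple(self):
        padded, rec = pad_to_stride(np.zeros((584, 565, 3), dtype=np.float32))
        assert padded.shape[:2] == (608, 576)
        assert (rec.height, rec.width) == (584, 565)

    def test_pad_then_crop_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((70, 93, 3)).astype(np.float32)
        padded, rec = pad_to_stride(img)
        np.testing.assert_array_equal(crop_back(padded, rec), img)

    def test_split_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_indices(10, (0.5, 0.2, 0.2), seed=0)
        idx = split_indices(10, (0.8, 0.2, 0.0), seed=0)
        assert len(idx["train"]) == 8 and len(idx["val"]) == 2

    def test_mixed_sizes_cannot_batch(self):
        with pytest.raises(ValueError, match="mixed"):
            to_batch([np.zeros((32, 32, 3)), np.zeros((64, 64, 3))])


def _tiny_records(n, seed, hw=(64, 64)):
    from mhanet import default_spec, make_dataset

    return make_dataset(n, default_spec("polyp", size=hw), seed=seed)


class TestTrainingLoop:
    def test_loss_decreases(self, fitted_tiny):
        losses = fitted_tiny.history_.losses
        assert losses[-1] < losses[0]

    def test_identical_seeds_identical_runlogs(self):
        recs = _tiny_records(4, seed=21)
        logs = []
        for _ in range(2):
            model = assemble_mhanet(ModelConfig(width_scale=0.25, seed=5))
            _, log = train(model, recs, [], TrainConfig(epochs=2, batch_size=2, seed=5))
            logs.append(log.losses)
        assert logs[0] == logs[1]

    def test_validation_selects_best_checkpoint(self):
        recs = _tiny_records(6, seed=22)
        model = assemble_mhanet(ModelConfig(width_scale=0.25, seed=6))
        best, log = train(model, recs[:4], recs[4:], TrainConfig(epochs=2, batch_size=2, seed=6))
        assert all("val_dice" in e for e in log.epochs)
        best_epoch_dice = max(e["val_dice"] for e in log.epochs)
        model.load_state_dict(best)
        assert mean_val_dice(model, recs[4:], 0.5) == pytest.approx(best_epoch_dice, abs=1e-6)

    def test_invalid_train_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-1)


class TestCheckpointAndEvaluate:
    def test_checkpoint_roundtrip_preserves_predictions(self, tmp_path, fitted_tiny):
        model = fitted_tiny.model_
        path = save_checkpoint(model.config, model.state_dict(), tmp_path / "ck.npz")
        restored = load_checkpoint(path)
        x = np.random.default_rng(1).random((1, 3, 64, 64)).astype(np.float32)
        np.testing.assert_array_equal(model.predict_proba(x), restored.predict_proba(x))
        assert restored.config == model.config

    def test_evaluate_with_ground_truth_oracle_is_perfect(self, fitted_tiny, monkeypatch):
        recs = _tiny_records(2, seed=23)
        model = fitted_tiny.model_
        # replace the network's probabilities with the ground truth per image
        truth_iter = iter([r.mask for r in recs] )
        monkeypatch.setattr(
            type(model), "predict_proba", lambda self, x: next(truth_iter)[None, None].astype(float)
        )
        per_image, agg = evaluate(model, recs)
        for rep in per_image.values():
            assert rep.dc == rep.ir == rep.ac == 1.0
        assert agg["dc"] == agg["miou"] == 1.0

    def test_macro_aggregate_is_mean_of_per_image(self, fitted_tiny):
        recs = _tiny_records(3, seed=24)
        per_image, agg = evaluate(fitted_tiny.model_, recs)
        assert agg["dc"] == pytest.approx(np.mean([r.dc for r in per_image.values()]))


class TestPredictFiles:
    def test_predict_writes_consistent_outputs(self, tmp_path, fitted_tiny):
        # non-divisible input exercises the pad -> predict -> crop path
        rng = np.random.default_rng(2)
        img8 = (rng.random((70, 90, 3)) * 255).astype(np.uint8)
        img_path = tmp_path / "img.png"
        Image.fromarray(img8).save(img_path)
        prob_path, mask_path = predict(fitted_tiny.model_, img_path, tmp_path, threshold=0.5)
        prob = np.asarray(Image.open(prob_path))
        mask = np.asarray(Image.open(mask_path))
        assert prob.shape == mask.shape == (70, 90)  # crop-back contract
        assert set(np.unique(mask)) <= {0, 255}
        # re-thresholding the stored probability map reproduces the mask
        np.testing.assert_array_equal((prob / 65535.0 >= 0.5), mask > 0)

    def test_unreadable_image_errors_with_path(self, tmp_path, fitted_tiny):
        bad = tmp_path / "corrupt.png"
        bad.write_bytes(b"not a png")
        with pytest.raises(OSError, match="corrupt.png"):
            predict(fitted_tiny.model_, bad, tmp_path)
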