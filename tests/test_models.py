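"""Classifier architectures, learning-rate schedule and training loop."""

import numpy as np
import pytest

from podquant import models, nn
from podquant.models import (LeNetConfig, DenseNetConfig, TrainConfig,
                             build_model, lr_schedule, train_classifier,
                             predict_proba, save_model, load_model)


def _toy_patchset(n_per_class=8, seed=0, size=32):
    """Four trivially separable classes: distinct mean intensities."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for cls in range(4):
        base = 0.8 * (cls - 1.5)  # well separated in normalized units
        xs.append(rng.normal(base, 0.1, (n_per_class, size, size, 3)))
        ys.extend([cls] * n_per_class)
    return np.concatenate(xs).astype(np.float32), np.array(ys)


class TestArchitectures:
    def test_softmax_rows_sum_to_one(self):
        x, _ = _toy_patchset(2)
        for config in (LeNetConfig(), DenseNetConfig(layers_per_block=2)):
            model = build_model(config, seed=0)
            probs = predict_proba(model, x)
            assert probs.shape == (x.shape[0], 4)
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_densenet_block_feature_sizes(self):
        model = build_model(DenseNetConfig(layers_per_block=2), seed=0)
        x, _ = _toy_patchset(1)
        shapes = model.block_io_shapes(x[:4])
        assert [s[1] for s in shapes] == [32, 16, 8]

    def test_densenet_channel_growth(self):
        # entering block b: 16 + (b-1) * layers_per_block * k, transitions
        # preserving channel count through their 1x1 convolution
        lpb, k = 2, 12
        model = build_model(DenseNetConfig(layers_per_block=lpb), seed=0)
        x, _ = _toy_patchset(1)
        shapes = model.block_io_shapes(x[:2])
        assert [s[0] for s in shapes] == [16, 16 + lpb * k, 16 + 2 * lpb * k]

    def test_wrong_input_shape_rejected(self):
        model = build_model(LeNetConfig(), seed=0)
        with pytest.raises(ValueError):
            predict_proba(model, np.zeros((2, 28, 28, 3), dtype=np.float32))

    def test_lenet_layer_pattern(self):
        model = build_model(LeNetConfig(), seed=0)
        kinds = [type(l).__name__ for l in model.net.layers]
        assert kinds == ["Conv2d", "MaxPool2", "Conv2d", "MaxPool2",
                         "Flatten", "Dense", "ReLU", "Dense"]


class TestLrSchedule:
    @pytest.mark.parametrize("epoch,expected", [
        (0, 1e-3), (9, 1e-3), (10, 1e-4), (19, 1e-4), (20, 1e-5), (29, 1e-5),
    ])
    def test_thirds_for_thirty_epochs(self, epoch, expected):
        cfg = TrainConfig(epochs=30)
        assert lr_schedule(epoch, cfg) == pytest.approx(expected)

    @pytest.mark.parametrize("epoch,expected", [
        (4, 1e-3), (5, 1e-4), (9, 1e-4), (10, 1e-5), (14, 1e-5),
    ])
    def test_thirds_for_fifteen_epochs(self, epoch, expected):
        cfg = TrainConfig(epochs=15)
        assert lr_schedule(epoch, cfg) == pytest.approx(expected)

    def test_last_epoch_is_two_steps_down(self):
        for epochs in (10, 15, 30, 7):
            cfg = TrainConfig(epochs=epochs)
            assert lr_schedule(epochs - 1, cfg) == pytest.approx(1e-5)

    def test_epoch_out_of_range(self):
        with pytest.raises(ValueError):
            lr_schedule(30, TrainConfig(epochs=30))


class TestTraining:
    def test_training_reduces_loss(self):
        x, y = _toy_patchset(8)
        model = build_model(LeNetConfig(), seed=0)
        logits0 = model.predict_logits(x)
        loss0, _ = nn.softmax_cross_entropy(logits0, y)
        cfg = TrainConfig(epochs=2, batch_size=8, seed=0)
        model, hist = train_classifier(model, (x, y), (x, y), cfg)
        assert min(h["val_loss"] for h in hist) < loss0

    def test_seeded_rerun_reproduces_history(self):
        x, y = _toy_patchset(4)
        cfg = TrainConfig(epochs=2, batch_size=8, seed=3)
        _, h1 = train_classifier(build_model(LeNetConfig(), seed=1),
                                 (x, y), (x, y), cfg)
        _, h2 = train_classifier(build_model(LeNetConfig(), seed=1),
                                 (x, y), (x, y), cfg)
        assert h1 == h2

    def test_empty_split_rejected(self):
        x, y = _toy_patchset(2)
        empty = (np.zeros((0, 32, 32, 3), dtype=np.float32),
                 np.zeros(0, dtype=int))
        with pytest.raises(ValueError):
            train_classifier(build_model(LeNetConfig(), seed=0),
                             empty, (x, y), TrainConfig(epochs=1))

    def test_separable_toy_problem_learned(self):
        x, y = _toy_patchset(16)
        xv, yv = _toy_patchset(8, seed=9)
        cfg = TrainConfig(epochs=6, batch_size=8, seed=0)
        model, hist = train_classifier(build_model(LeNetConfig(), seed=0),
                                       (x, y), (xv, yv), cfg)
        assert max(h["val_accuracy"] for h in hist) >= 0.95


class TestInference:
    def test_duplicate_patch_identical_rows(self):
        x, _ = _toy_patchset(1)
        batch = np.stack([x[0], x[1], x[0]])
        model = build_model(DenseNetConfig(layers_per_block=2), seed=0)
        probs = predict_proba(model, batch)
        np.testing.assert_array_equal(probs[0], probs[2])

    def test_permutation_equivariance(self):
        x, _ = _toy_patchset(3)
        model = build_model(LeNetConfig(), seed=0)
        probs = predict_proba(model, x)
        perm = np.random.default_rng(0).permutation(len(x))
        np.testing.assert_allclose(predict_proba(model, x[perm]), probs[perm],
                                   atol=1e-6)

    def test_argmax_in_class_range(self):
        x, _ = _toy_patchset(2)
        model = build_model(DenseNetConfig(layers_per_block=2), seed=0)
        assert set(predict_proba(model, x).argmax(axis=1)) <= {0, 1, 2, 3}


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        from podquant.patches import NormalizationStats
        x, y = _toy_patchset(2)
        model = build_model(DenseNetConfig(layers_per_block=2), seed=0)
        cfg = TrainConfig(epochs=1, batch_size=8, seed=0)
        model, _ = train_classifier(model, (x, y), (x, y), cfg)
        stats = NormalizationStats(channel_means=np.array([1.0, 2.0, 3.0]),
                                   channel_sds=np.array([4.0, 5.0, 6.0]),
                                   mean_patch=np.zeros((32, 32, 3)))
        path = tmp_path / "model.npz"
        save_model(path, model, cfg, stats)
        loaded, train_cfg, loaded_stats = load_model(path)
        np.testing.assert_allclose(predict_proba(loaded, x),
                                   predict_proba(model, x), atol=1e-6)
        assert train_cfg == cfg
        np.testing.assert_allclose(loaded_stats.channel_sds, stats.channel_sds)

    def test_pretrained_init_loaded_from_file(self, tmp_path):
        x, y = _toy_patchset(2)
        donor = build_model(LeNetConfig(), seed=5)
        path = tmp_path / "donor.npz"
        save_model(path, donor)
        cfg = TrainConfig(epochs=1, batch_size=8, seed=0, base_lr=0.0,
                          init_weights=str(path))
        model, _ = train_classifier(build_model(LeNetConfig(), seed=0),
                                    (x, y), (x, y), cfg)
        # zero learning rate: weights stay at the donor initialization
        np.testing.assert_allclose(predict_proba(model, x),
                                   predict_proba(donor, x), atol=1e-5)
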