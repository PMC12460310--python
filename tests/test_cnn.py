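"""Residual network building blocks, training behaviour and metrics."""

import numpy as np
import pytest

from fcbtrace import (ConfusionMatrix, ResNetConfig, build_resnet12, evaluate,
                      fixture_confusion, metrics, smooth_curve, train)
from fcbtrace.cnn import _Block, softmax


class TestArchitecture:
    def test_softmax_probability_vector_on_zero_image(self):
        model = build_resnet12(ResNetConfig(input_size=(32, 32), seed=0))
        p = model.predict_proba(np.zeros((1, 32, 32)))
        assert p.shape == (1, 5)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)
        assert (p >= 0).all()

    def test_softmax_sums_to_one_random_inputs(self, rng):
        p = softmax(rng.standard_normal((20, 5)) * 10)
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-6

    def test_identity_block_with_zero_weights_is_relu(self, rng):
        blk = _Block(8, 8, downsample=False, rng=rng, name="t")
        for conv in (blk.conv1, blk.conv2):
            conv.W[:] = 0
            conv.b[:] = 0
        x = rng.standard_normal((2, 8, 6, 6)).astype(np.float32)
        out = blk.forward(x, training=False)
        assert np.allclose(out, np.maximum(x, 0), atol=1e-6)

    def test_twelve_counted_layers(self):
        model = build_resnet12(ResNetConfig())
        assert model.n_counted_layers() == 12
        audit = model.layer_audit()
        # the two projection shortcuts carry parameters but are not counted
        assert (~audit["counted"]).sum() == 2

    def test_parameter_count_matches_hand_tally(self):
        """Layer-by-layer arithmetic for the default 16-16-32-32-64 schedule."""
        stem = 3 * 3 * 1 * 16 + 16 + 2 * 16                       # conv + bn
        b1 = 2 * (3 * 3 * 16 * 16 + 16) + 2 * (2 * 16)            # identity 16
        b2 = ((3 * 3 * 16 * 32 + 32) + (3 * 3 * 32 * 32 + 32)
              + 2 * (2 * 32) + (1 * 1 * 16 * 32 + 32) + 2 * 32)   # down 16->32
        b3 = 2 * (3 * 3 * 32 * 32 + 32) + 2 * (2 * 32)            # identity 32
        b4 = ((3 * 3 * 32 * 64 + 64) + (3 * 3 * 64 * 64 + 64)
              + 2 * (2 * 64) + (1 * 1 * 32 * 64 + 64) + 2 * 64)   # down 32->64
        b5 = 2 * (3 * 3 * 64 * 64 + 64) + 2 * (2 * 64)            # identity 64
        head = 64 * 5 + 5
        model = build_resnet12(ResNetConfig())
        assert model.n_parameters() == stem + b1 + b2 + b3 + b4 + b5 + head

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="downsampling"):
            ResNetConfig(input_size=(8, 8))


class TestTraining:
    def test_memorizes_two_images(self, rng):
        x = rng.uniform(0, 1, (2, 32, 32)).astype(np.float32)
        y = np.array([0, 1])
        cfg = ResNetConfig(n_classes=2, input_size=(32, 32), epochs=60,
                           batch_size=2, seed=0, stop_when_test_perfect=True)
        model = build_resnet12(cfg)
        curves = train(model, x, y, x, y)
        assert max(curves.test_acc) == 1.0

    def test_weight_decay_zero_does_not_increase_final_loss(self, rng):
        x = rng.uniform(0, 1, (2, 32, 32)).astype(np.float32)
        y = np.array([0, 1])
        losses = {}
        for wd in (1e-4, 0.0):
            cfg = ResNetConfig(n_classes=2, input_size=(32, 32), epochs=40,
                               batch_size=2, seed=0, weight_decay=wd,
                               stop_when_test_perfect=False)
            model = build_resnet12(cfg)
            curves = train(model, x, y)
            losses[wd] = curves.train_loss[-1]
        assert losses[0.0] <= losses[1e-4] + 1e-3

    def test_shuffled_labels_give_chance_accuracy(self, rng):
        """Permutation null: ~20% test accuracy for 5 classes."""
        accs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.uniform(0, 1, (40, 32, 32)).astype(np.float32)
            y = r.integers(0, 5, 40)
            xt = r.uniform(0, 1, (25, 32, 32)).astype(np.float32)
            yt = r.integers(0, 5, 25)
            cfg = ResNetConfig(input_size=(32, 32), epochs=6, seed=seed,
                               stop_when_test_perfect=False)
            model = build_resnet12(cfg)
            train(model, x, y)
            accs.append(float(np.mean(model.predict(xt) == yt)))
        assert abs(np.mean(accs) - 0.2) <= 0.1

    def test_reproducible_curves(self, rng):
        x = rng.uniform(0, 1, (8, 32, 32)).astype(np.float32)
        y = np.tile([0, 1], 4)
        runs = []
        for _ in range(2):
            cfg = ResNetConfig(n_classes=2, input_size=(32, 32), epochs=3,
                               seed=5, stop_when_test_perfect=False)
            model = build_resnet12(cfg)
            runs.append(train(model, x, y).train_loss)
        assert runs[0] == runs[1]

    def test_checkpoint_round_trip(self, rng, tmp_path):
        from fcbtrace.cnn import ResNet12

        x = rng.uniform(0, 1, (6, 32, 32)).astype(np.float32)
        y = np.tile([0, 1, 2], 2)
        cfg = ResNetConfig(n_classes=3, input_size=(32, 32), epochs=2,
                           seed=1, stop_when_test_perfect=False)
        model = build_resnet12(cfg)
        train(model, x, y)
        model.save(tmp_path / "ckpt.npz")
        back = ResNet12.load(tmp_path / "ckpt.npz")
        assert back.config == cfg
        assert np.array_equal(back.predict_proba(x), model.predict_proba(x))

    def test_bad_labels_rejected(self, rng):
        x = rng.uniform(0, 1, (4, 32, 32)).astype(np.float32)
        model = build_resnet12(ResNetConfig(input_size=(32, 32)))
        with pytest.raises(ValueError, match="label"):
            train(model, x, np.array([0, 1, 2, 7]))
        with pytest.raises(ValueError, match="label"):
            evaluate(model, x, np.array([0, 1, 2, 7]))


class TestMetrics:
    def test_fixture_confusion_accuracy(self):
        m = metrics(fixture_confusion())
        assert m["accuracy"] == pytest.approx(13 / 15)
        assert round(100 * m["accuracy"], 3) == 86.667

    def test_perfect_diagonal(self):
        m = metrics(ConfusionMatrix(np.diag([4, 2, 3])))
        assert m["accuracy"] == 1.0
        assert (m["per_class"] == 1.0).all().all()
        assert m["macro_precision"] == m["macro_sensitivity"] == 1.0

    def test_matches_per_sample_tally_oracle(self, rng):
        counts = rng.integers(0, 6, (5, 5))
        conf = ConfusionMatrix(counts)
        m = metrics(conf)
        # enumerate individual (true, pred) pairs and tally one-vs-rest
        pairs = [(t, p) for t in range(5) for p in range(5)
                 for _ in range(counts[t, p])]
        total = len(pairs)
        acc = sum(t == p for t, p in pairs) / total
        assert m["accuracy"] == pytest.approx(acc)
        for c in range(5):
            tp = sum(1 for t, p in pairs if t == c and p == c)
            fp = sum(1 for t, p in pairs if t != c and p == c)
            fn = sum(1 for t, p in pairs if t == c and p != c)
            tn = total - tp - fp - fn
            row = m["per_class"].iloc[c]
            if tp + fp:
                assert row["precision"] == pytest.approx(tp / (tp + fp))
            if tp + fn:
                assert row["sensitivity"] == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert row["specificity"] == pytest.approx(tn / (tn + fp))

    def test_tp_sum_equals_trace_and_permutation_invariance(self, rng):
        counts = rng.integers(0, 9, (4, 4))
        conf = ConfusionMatrix(counts)
        m = metrics(conf)
        assert m["accuracy"] == pytest.approx(np.trace(counts) / counts.sum())
        perm = rng.permutation(4)
        m2 = metrics(ConfusionMatrix(counts[np.ix_(perm, perm)]))
        assert m2["accuracy"] == pytest.approx(m["accuracy"])

    def test_zero_over_zero_flagged(self):
        counts = np.array([[2, 0], [3, 0]])  # class 1 never predicted, never right
        m = metrics(ConfusionMatrix(counts))
        assert ("1", "precision") in m["undefined"]
        assert np.isnan(m["per_class"].iloc[1]["precision"])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics(ConfusionMatrix(np.zeros((3, 3), dtype=int)))

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(np.array([[0.5, 0], [0, 1]]))


class TestSmoothing:
    def test_constant_series_fixed_point(self):
        v = np.full(10, 3.5)
        assert np.array_equal(smooth_curve(v, 0.6), v)

    def test_alpha_zero_identity(self, rng):
        v = rng.standard_normal(20)
        assert np.array_equal(smooth_curve(v, 0.0), v)

    def test_two_point_recurrence(self):
        assert np.allclose(smooth_curve([0.0, 1.0], 0.6), [0.0, 0.4])

    def test_smoothed_within_raw_range(self, rng):
        v = rng.standard_normal(50)
        s = smooth_curve(v, 0.6)
        assert s.min() >= v.min() - 1e-12 and s.max() <= v.max() + 1e-12

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            smooth_curve([1.0, 2.0], 1.0)
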