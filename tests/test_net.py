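"""Dense V-Net: shapes, loss, gradients, training and inference."""

import numpy as np
import pytest

from mfiseg.net import (
    DenseVNet,
    DenseVNetConfig,
    TrainingConfig,
    dice_hinge_loss,
    one_hot,
    preprocess,
    segment,
    softmax,
    train,
)
from mfiseg.net.losses import dlogits_from_dprobs, soft_dice_per_class

TINY = DenseVNetConfig(
    input_channels=1,
    n_classes=3,
    growth=(2, 2),
    block_layers=(1, 2),
    dilations=((1,), (1, 2)),
    down_factor=(2, 2, 2),
    dropout_rate=0.0,
)


class TestModel:
    def test_output_shape_matches_input_with_class_channels(self, rng):
        model = DenseVNet(TINY, seed=0)
        x = rng.normal(size=(2, 1, 8, 12, 4)).astype(np.float32)
        y = model.forward(x)
        assert y.shape == (2, 3, 8, 12, 4)

    def test_parameter_count_pure_function_of_config(self):
        a = DenseVNet(TINY, seed=0).n_parameters()
        b = DenseVNet(TINY, seed=99).n_parameters()
        assert a == b > 0

    def test_forward_deterministic_without_dropout(self, rng):
        model = DenseVNet(TINY, seed=1)
        x = rng.normal(size=(1, 1, 8, 8, 4)).astype(np.float32)
        assert np.array_equal(model.forward(x), model.forward(x))

    def test_indivisible_window_rejected(self, rng):
        model = DenseVNet(TINY, seed=0)
        x = rng.normal(size=(1, 1, 7, 8, 4)).astype(np.float32)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(x)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        model = DenseVNet(TINY, seed=5)
        x = rng.normal(size=(1, 1, 8, 8, 4)).astype(np.float32)
        before = model.forward(x)
        path = tmp_path / "m.npz"
        model.save(path)
        loaded = DenseVNet.load(path)
        assert np.allclose(loaded.forward(x), before, atol=1e-6)


class TestDiceHingeLoss:
    def test_perfect_prediction_gives_zero(self, rng):
        labels = rng.integers(0, 3, (1, 4, 4, 2))
        target = one_hot(labels, 3)
        loss, grad = dice_hinge_loss(target, target, hinge_margin=0.0)
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_uniform_prediction_closed_form(self):
        # p = 0.5 everywhere over 2 classes; target all class 1 on N voxels:
        # soft Dice for class 1 = (2*0.5N)/(0.5N + N) = 2/3, loss 1/3
        n = 4 * 4 * 2
        probs = np.full((1, 2, 4, 4, 2), 0.5, dtype=np.float32)
        target = one_hot(np.ones((1, 4, 4, 2), dtype=np.int64), 2)
        loss, _ = dice_hinge_loss(probs, target, hinge_margin=0.0)
        assert loss == pytest.approx(1 / 3, abs=1e-4)

    def test_loss_decreases_toward_target(self):
        target = one_hot(np.array([[[[1]], [[0]]]], dtype=np.int64), 2)  # (1,2,1,1)
        losses = []
        for alpha in np.linspace(0.05, 0.95, 7):
            probs = np.empty_like(target)
            probs[:, 1] = alpha * target[:, 1] + (1 - alpha) * target[:, 0]
            probs[:, 0] = 1.0 - probs[:, 1]
            loss, _ = dice_hinge_loss(probs, target, hinge_margin=0.0)
            losses.append(loss)
        assert np.all(np.diff(losses) < 0)

    def test_hinge_clamps_well_fitted_classes(self, rng):
        labels = rng.integers(0, 3, (1, 4, 4, 2))
        target = one_hot(labels, 3)
        loss, grad = dice_hinge_loss(target, target, hinge_margin=0.1)
        assert loss == 0.0
        assert np.all(grad == 0.0)

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.normal(size=(1, 3, 4, 4, 2)).astype(np.float64)
        target = one_hot(rng.integers(0, 3, (1, 4, 4, 2)), 3)

        def loss_of(z):
            p = softmax(z)
            l, dp = dice_hinge_loss(p, target, hinge_margin=0.0)
            return l, dlogits_from_dprobs(p, dp)

        base, grad = loss_of(logits)
        rng2 = np.random.default_rng(0)
        for _ in range(10):
            idx = tuple(rng2.integers(0, s) for s in logits.shape)
            eps = 1e-5
            zp = logits.copy()
            zp[idx] += eps
            zm = logits.copy()
            zm[idx] -= eps
            num = (loss_of(zp)[0] - loss_of(zm)[0]) / (2 * eps)
            assert num == pytest.approx(float(grad[idx]), abs=1e-5)


class TestModelGradients:
    def test_backprop_matches_finite_differences(self, rng):
        model = DenseVNet(TINY, seed=0)
        x = rng.normal(size=(2, 1, 8, 8, 4)).astype(np.float32)
        target = one_hot(rng.integers(0, 3, (2, 8, 8, 4)), 3)

        def loss_of():
            logits = model.forward(x, training=True)
            p = softmax(logits)
            l, dp = dice_hinge_loss(p, target, hinge_margin=0.0)
            return l, dlogits_from_dprobs(p, dp)

        _, dlog = loss_of()
        model.backward(dlog)
        grads = [g.copy() for g in model.grads]
        rng2 = np.random.default_rng(1)
        checked = 0
        for pi, p in enumerate(model.params):
            flat = p.reshape(-1)
            j = int(rng2.integers(flat.size))
            ana = grads[pi].reshape(-1)[j]
            if abs(ana) < 1e-4:  # below float32 finite-difference noise
                continue
            eps = 1e-3
            orig = flat[j]
            flat[j] = orig + eps
            lp, _ = loss_of()
            flat[j] = orig - eps
            lm, _ = loss_of()
            flat[j] = orig
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(float(ana), rel=0.05, abs=1e-4)
            checked += 1
        assert checked >= 3


def _blob_dataset(n, seed, shape=(16, 16, 8)):
    """Tiny two-class blobs separable by intensity and position."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        labels = np.zeros(shape, dtype=np.int64)
        cx = int(rng.integers(4, shape[0] - 4))
        labels[cx - 3:cx + 3, 4:12, 2:6] = 1
        img = rng.normal(0.0, 0.1, shape) + labels
        out.append((img[None].astype(np.float32), labels))
    return out


class TestTraining:
    def test_loss_decreases_on_toy_task(self):
        data = _blob_dataset(4, seed=0)
        cfg_m = DenseVNetConfig(
            input_channels=1, n_classes=2, growth=(3, 4), block_layers=(1, 1),
            dilations=((1,), (1,)), dropout_rate=0.0,
        )
        model = DenseVNet(cfg_m, seed=0)
        cfg = TrainingConfig(
            max_iterations=40, batch_size=2, window_shape=(16, 16, 8),
            val_interval=40, seed=0,
        )
        history = train(model, data, cfg)
        first = np.mean(history["loss"][:5])
        last = np.mean(history["loss"][-5:])
        assert last < first

    def test_identical_seeds_identical_traces(self):
        data = _blob_dataset(3, seed=2)
        cfg_m = DenseVNetConfig(
            input_channels=1, n_classes=2, growth=(2, 2), block_layers=(1, 1),
            dilations=((1,), (1,)), dropout_rate=0.2,
        )
        cfg = TrainingConfig(
            max_iterations=15, batch_size=2, window_shape=(16, 16, 8),
            val_interval=15, seed=7,
        )
        h1 = train(DenseVNet(cfg_m, seed=3), data, cfg)
        h2 = train(DenseVNet(cfg_m, seed=3), data, cfg)
        assert h1["loss"] == h2["loss"]
        assert h1["val_dice"] == h2["val_dice"]

    def test_empty_dataset_rejected(self):
        model = DenseVNet(TINY, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(model, [], TrainingConfig(max_iterations=1))


class TestPreprocess:
    def test_identity_at_target_spacing(self, rng):
        img = rng.normal(size=(8, 8, 4))
        mask = rng.integers(0, 3, (8, 8, 4))
        (out,), m, sp = preprocess([img], mask, spacing=(0.7, 0.7, 3.0))
        assert np.array_equal(out, img)
        assert np.array_equal(m, mask)
        assert sp == (0.7, 0.7, 3.0)

    def test_label_set_preserved_under_resampling(self, noiseless_phantom):
        _, mask, _ = noiseless_phantom
        _, m, _ = preprocess(
            [mask.labels.astype(float)], mask.labels,
            spacing=(1.4, 1.4, 3.0), target_spacing=(0.7, 0.7, 3.0),
        )
        assert set(np.unique(m)) <= set(np.unique(mask.labels))

    def test_volume_preserved_across_inplane_resample(self):
        cube = np.zeros((64, 64, 8), dtype=np.int16)
        cube[16:48, 16:48, 2:6] = 1
        _, m, _ = preprocess(
            [cube.astype(float)], cube, spacing=(1.4, 1.4, 3.0),
            target_spacing=(0.7, 0.7, 3.0),
        )
        v0 = (cube == 1).sum() * 1.4 * 1.4 * 3.0
        v1 = (m == 1).sum() * 0.7 * 0.7 * 3.0
        assert v1 == pytest.approx(v0, rel=0.03)

    def test_pad_smaller_than_data_rejected(self, rng):
        img = rng.normal(size=(8, 8, 4))
        with pytest.raises(ValueError, match="crop"):
            preprocess([img], None, (1, 1, 1), (1, 1, 1), pad_to=(4, 8, 4))


class TestSegment:
    def test_probabilities_sum_to_one_and_labels_in_range(self, rng):
        model = DenseVNet(TINY, seed=0)
        x = rng.normal(size=(1, 8, 8, 4)).astype(np.float32)
        seg = segment(model, x)
        assert np.allclose(seg.probabilities.sum(axis=0), 1.0, atol=1e-5)
        assert set(np.unique(seg.hard_labels())) <= {0, 1, 2}

    def test_tiling_covers_large_volume(self, rng):
        model = DenseVNet(TINY, seed=0)
        x = rng.normal(size=(1, 16, 16, 8)).astype(np.float32)
        seg = segment(model, x, window_shape=(8, 8, 4))
        assert seg.probabilities.shape == (3, 16, 16, 8)
        assert np.allclose(seg.probabilities.sum(axis=0), 1.0, atol=1e-5)

    def test_label_lookup_applied(self, rng):
        model = DenseVNet(TINY, seed=0)
        x = rng.normal(size=(1, 8, 8, 4)).astype(np.float32)
        seg = segment(model, x, index_to_label={0: 0, 1: 7, 2: 9})
        assert set(np.unique(seg.hard_labels())) <= {0, 7, 9}

    def test_channel_mismatch_rejected(self, rng):
        model = DenseVNet(TINY, seed=0)
        with pytest.raises(ValueError, match="channels"):
            segment(model, rng.normal(size=(2, 8, 8, 4)).astype(np.float32))
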