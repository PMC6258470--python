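import numpy as np
import pytest

import rnaqa._nn as nn
from rnaqa import (
    ModelSpec,
    TrainingSchedule,
    build_model,
    count_parameters,
    load_model,
    next_learning_rate,
    predict,
    save_model,
    train,
)
from rnaqa.errors import ModelError, ShapeError

from .oracles import direct_conv3d


def hand_count(spec: ModelSpec) -> int:
    """Independent parameter count: (k^3 c_in + 1) c_out and (f_in + 1) f_out."""
    total = 0
    c_in = spec.input_channels
    size = spec.grid_edge
    for i, (c_out, k) in enumerate(zip(spec.conv_filters, spec.conv_kernels), 1):
        total += (k**3 * c_in + 1) * c_out
        size = size - k + 1
        if i == spec.pool_after_layer:
            size //= spec.pool_size
        c_in = c_out
    features = c_in * size**3
    total += (features + 1) * spec.dense_units
    total += (spec.dense_units + 1) * spec.output_units
    return total


class TestArchitecture:
    def test_reference_parameter_count(self):
        model = build_model(ModelSpec.reference(), seed=0)
        assert count_parameters(model) == 4_282_801

    def test_reference_shape_trace(self):
        assert ModelSpec.reference().shape_trace() == [32, 28, 24, 12, 10, 8]

    @pytest.mark.parametrize("spec", [
        ModelSpec(conv_filters=(2,), conv_kernels=(3,), pool_after_layer=0,
                  dense_units=1, input_channels=1, grid_edge=4,
                  dropout_layers=frozenset()),
        ModelSpec.desk_scale(),
    ])
    def test_count_matches_hand_formula(self, spec):
        model = build_model(spec, seed=0)
        assert count_parameters(model) == hand_count(spec)

    def test_toy_spec_frozen_count(self):
        # conv (27*1+1)*2 = 56; dense (2*8+1)*1 = 17; out (1+1)*1 = 2
        spec = ModelSpec(conv_filters=(2,), conv_kernels=(3,),
                         pool_after_layer=0, dense_units=1, input_channels=1,
                         grid_edge=4, dropout_layers=frozenset())
        assert count_parameters(build_model(spec, seed=0)) == 75

    def test_spatial_underflow_raises(self):
        spec = ModelSpec(conv_filters=(4, 4), conv_kernels=(5, 5),
                         pool_after_layer=0, grid_edge=8)
        with pytest.raises(ShapeError, match="conv2"):
            spec.shape_trace()

    def test_seeded_initialization_deterministic(self, tiny_spec):
        w1 = [p.copy() for p, _ in build_model(tiny_spec, 7).network.parameters()]
        w2 = [p for p, _ in build_model(tiny_spec, 7).network.parameters()]
        w3 = [p for p, _ in build_model(tiny_spec, 8).network.parameters()]
        assert all(np.array_equal(a, b) for a, b in zip(w1, w2))
        assert any(not np.array_equal(a, b) for a, b in zip(w1, w3))

    def test_biases_start_at_zero(self, tiny_spec):
        model = build_model(tiny_spec, seed=0)
        for layer in model.network.layers:
            if hasattr(layer, "b"):
                assert not layer.b.any()


class TestConvKernels:
    def test_forward_matches_direct_convolution(self):
        rng = np.random.default_rng(0)
        conv = nn.Conv3d(2, 3, 3, rng, dtype=np.float64)
        x = np.random.default_rng(1).random((2, 2, 6, 6, 6))
        expected = direct_conv3d(x, conv.W, conv.b)
        assert np.allclose(conv.forward(x), expected, atol=1e-10)

    def test_numba_and_im2col_paths_agree(self, monkeypatch):
        rng = np.random.default_rng(0)
        conv = nn.Conv3d(3, 4, 3, rng, dtype=np.float64)
        x = np.random.default_rng(1).random((2, 3, 7, 7, 7))
        gy = np.random.default_rng(2).random((2, 4, 5, 5, 5))

        y_fast = conv.forward(x, training=True)
        gx_fast = conv.backward(gy)
        gw_fast = conv.grads[0].copy()

        monkeypatch.setattr(nn, "_conv_kernels", None)
        conv.grads[0][...] = 0
        conv.grads[1][...] = 0
        y_ref = conv.forward(x, training=True)
        gx_ref = conv.backward(gy)
        assert np.allclose(y_fast, y_ref, atol=1e-10)
        assert np.allclose(gx_fast, gx_ref, atol=1e-10)
        assert np.allclose(gw_fast, conv.grads[0], atol=1e-10)

    def test_backprop_matches_finite_differences(self, tiny_spec):
        model = build_model(tiny_spec, seed=1, dtype=np.float64)
        net = model.network
        rng = np.random.default_rng(0)
        x = rng.random((2, 2, 8, 8, 8))
        y = rng.random(2)

        net.zero_grads()
        pred = net.forward(x, training=True, rng=rng).ravel()
        net.backward(((2.0 / len(y)) * (pred - y))[:, None])

        def loss():
            return float(np.mean((net.forward(x).ravel() - y) ** 2))

        h = 1e-6
        for p, g in list(net.parameters()):
            flat = p.ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + h
                up = loss()
                flat[i] = old - h
                down = loss()
                flat[i] = old
                fd = (up - down) / (2 * h)
                assert g.ravel()[i] == pytest.approx(fd, rel=1e-5, abs=1e-9)


class TestLearningRateSchedule:
    schedule = TrainingSchedule()

    def test_plateau_halves(self):
        history = [0.5] + [0.5] * 5  # five epochs with no strict improvement
        new_lr, stop = next_learning_rate(history, 0.05, self.schedule)
        assert new_lr == pytest.approx(0.025)
        assert not stop

    def test_improving_history_keeps_rate(self):
        history = [0.5, 0.4, 0.3, 0.2, 0.1, 0.05]
        new_lr, stop = next_learning_rate(history, 0.05, self.schedule)
        assert new_lr == 0.05 and not stop

    def test_patience_resets_after_reduction(self):
        history = [0.5] + [0.5] * 8
        # a reduction at epoch 5 restarts the counter: only 3 flat epochs since
        new_lr, stop = next_learning_rate(history, 0.025, self.schedule,
                                          last_reduction_epoch=5)
        assert new_lr == 0.025 and not stop

    def test_five_halvings_reach_stop(self):
        lr = 0.05
        last_reduction = -1
        history = [1.0]
        stop = False
        halvings = 0
        for epoch in range(1, 100):
            history.append(1.0)
            new_lr, stop = next_learning_rate(history, lr, self.schedule,
                                              last_reduction)
            if new_lr != lr:
                last_reduction = epoch
                lr = new_lr
                halvings += 1
            if stop:
                break
        assert halvings == 5
        assert lr == pytest.approx(0.0015625, rel=1e-12)
        assert stop


class TestTraining:
    def _samples(self, tiny_spec, n=32, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.random((n, tiny_spec.input_channels) +
                       (tiny_spec.grid_edge,) * 3).astype(np.float32)
        y = rng.random(n)
        return X, y

    def test_constant_target_regression(self, tiny_spec):
        X, _ = self._samples(tiny_spec)
        y = np.full(len(X), 0.5)
        model = build_model(tiny_spec, seed=0)
        train(model, (X, y), (X, y),
              TrainingSchedule(initial_lr=0.05, momentum=0.9, max_epochs=120,
                               stop_lr=1e-5, seed=0))
        assert model.training_history[-1]["train_mse"] < 1e-3
        preds = predict(model, list(X))
        assert np.max(np.abs(preds - 0.5)) < 0.05

    def test_seeded_training_is_reproducible(self, tiny_spec):
        X, y = self._samples(tiny_spec)
        weights = []
        for _ in range(2):
            model = build_model(tiny_spec, seed=0)
            train(model, (X, y), (X, y),
                  TrainingSchedule(initial_lr=0.01, max_epochs=3, seed=5))
            weights.append([p.copy() for p, _ in model.network.parameters()])
        assert all(np.array_equal(a, b) for a, b in zip(*weights))

    def test_zero_learning_rate_leaves_weights_unchanged(self, tiny_spec):
        X, y = self._samples(tiny_spec)
        model = build_model(tiny_spec, seed=0)
        before = [p.copy() for p, _ in model.network.parameters()]
        train(model, (X, y), (X, y),
              TrainingSchedule(initial_lr=0.0, stop_lr=0.0, max_epochs=2, seed=0))
        after = [p for p, _ in model.network.parameters()]
        assert all(np.array_equal(a, b) for a, b in zip(before, after))

    def test_loss_decreases_on_held_out_set(self, tiny_spec):
        X, y = self._samples(tiny_spec, n=48, seed=1)
        Xv, yv = self._samples(tiny_spec, n=16, seed=2)
        # held-out labels share the generating process of the training labels
        model = build_model(tiny_spec, seed=0)
        train(model, (X, y), (Xv, yv),
              TrainingSchedule(initial_lr=0.05, max_epochs=30, seed=0))
        history = model.training_history
        assert history[-1]["val_mse"] < history[0]["val_mse"]

    def test_unnormalized_labels_rejected(self, tiny_spec):
        X, _ = self._samples(tiny_spec)
        bad = np.full(len(X), 3.0)  # raw Å-scale labels, not in [0, 1]
        model = build_model(tiny_spec, seed=0)
        with pytest.raises(ModelError):
            train(model, (X, bad), (X, bad), TrainingSchedule(max_epochs=1))

    def test_empty_stream_rejected(self, tiny_spec):
        model = build_model(tiny_spec, seed=0)
        with pytest.raises(ModelError):
            train(model, [], [], TrainingSchedule(max_epochs=1))


class TestPredict:
    def test_deterministic_and_batch_consistent(self, tiny_spec):
        model = build_model(tiny_spec, seed=0)
        rng = np.random.default_rng(0)
        g1 = rng.random((2, 8, 8, 8)).astype(np.float32)
        g2 = rng.random((2, 8, 8, 8)).astype(np.float32)
        s1 = predict(model, g1)
        assert predict(model, g1) == s1
        batch = predict(model, [g1, g2])
        assert batch[0] == pytest.approx(s1, abs=1e-7)
        assert batch[1] == pytest.approx(predict(model, g2), abs=1e-7)

    def test_shape_mismatch_names_expected(self, tiny_spec):
        model = build_model(tiny_spec, seed=0)
        with pytest.raises(ModelError, match=r"\(2, 8, 8, 8\)"):
            predict(model, np.zeros((3, 32, 32, 32)))

    def test_unnormalized_grid_rejected(self, tiny_spec):
        from rnaqa import VoxelGrid
        model = build_model(
            ModelSpec(conv_filters=(2,), conv_kernels=(3,), pool_after_layer=0,
                      dense_units=2, input_channels=3, grid_edge=32,
                      dropout_layers=frozenset()), seed=0)
        grid = VoxelGrid(np.zeros((3, 32, 32, 32)), normalized=False)
        with pytest.raises(ModelError):
            predict(model, grid)


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_spec, tmp_path):
        from rnaqa import NormalizationStats
        model = build_model(tiny_spec, seed=0)
        model.normalization = NormalizationStats(
            channel_min=np.zeros(3), channel_max=np.array([4.0, 60.0, 1.0]),
            label_min=0.0, label_max=9.0)
        model.training_history = [{"epoch": 0, "train_mse": 0.1,
                                   "val_mse": 0.2, "lr": 0.05}]
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        x = np.random.default_rng(3).random(
            (2, tiny_spec.input_channels) + (tiny_spec.grid_edge,) * 3)
        assert np.allclose(predict(model, list(x)), predict(loaded, list(x)))
        assert loaded.normalization.label_max == 9.0
        assert loaded.training_history == model.training_history
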