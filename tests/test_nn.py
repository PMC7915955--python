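"""Autodiff ops, FC-DenseNet contracts, losses, and the training loop."""

import numpy as np
import pytest

import adaptseg.nn.autodiff as ad
from adaptseg.nn import (FCDenseNet3D, NetworkConfig, TrainConfig, build_network,
                         dual_cross_entropy, sigmoid_bce, softmax, train)
from adaptseg.nn.autodiff import (Var, avg_pool, concat, conv3d, relu,
                                  transposed_conv3d)
from adaptseg.nn.losses import dice_loss


@pytest.fixture
def f64(monkeypatch):
    """Run autodiff in float64 so finite differences are tight."""
    import adaptseg.nn.losses as losses_mod
    monkeypatch.setattr(ad, "DTYPE", np.float64)
    monkeypatch.setattr(losses_mod, "DTYPE", np.float64)
    yield


def numeric_grad(f, x, h=1e-6):
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + h
        fp = f()
        x[i] = old - h
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * h)
    return g


def check_op_gradients(build, inputs, tol=1e-5):
    """Compare analytic gradients of sum(weight * op(inputs)) to numeric."""
    rng = np.random.default_rng(0)
    for v in inputs:
        v.grad = None
    out = build(*inputs)
    w = rng.standard_normal(out.data.shape)
    loss = Var((out.data * w).sum(), parents=(out,))
    loss._backward = lambda g: out._accumulate(g * w)
    loss.backward()
    for v in inputs:
        def f(v=v):
            return float((build(*inputs).data * w).sum())
        num = numeric_grad(f, v.data)
        assert np.allclose(v.grad, num, atol=tol, rtol=1e-4), \
            f"gradient mismatch: max err {np.abs(v.grad - num).max()}"


class TestAutodiffGradients:
    def test_conv3d_gradients(self, f64):
        rng = np.random.default_rng(1)
        x = Var(rng.standard_normal((2, 4, 4, 3)), requires_grad=True)
        w = Var(0.3 * rng.standard_normal((3, 2, 3, 3, 3)), requires_grad=True)
        b = Var(rng.standard_normal(3), requires_grad=True)
        check_op_gradients(conv3d, (x, w, b))

    def test_transposed_conv_gradients(self, f64):
        rng = np.random.default_rng(2)
        x = Var(rng.standard_normal((2, 3, 3, 2)), requires_grad=True)
        w = Var(0.3 * rng.standard_normal((4, 2, 2, 2, 1)), requires_grad=True)
        b = Var(rng.standard_normal(4), requires_grad=True)
        check_op_gradients(lambda x, w, b: transposed_conv3d(x, w, b, (2, 2, 1)),
                           (x, w, b))

    def test_pool_relu_concat_gradients(self, f64):
        rng = np.random.default_rng(3)
        x = Var(rng.standard_normal((2, 4, 4, 2)), requires_grad=True)
        y = Var(rng.standard_normal((3, 4, 4, 2)), requires_grad=True)
        check_op_gradients(lambda x: avg_pool(x, (2, 2, 2)), (x,))
        check_op_gradients(relu, (x,))
        check_op_gradients(lambda x, y: concat([x, y]), (x, y))

    @pytest.mark.parametrize("fp_weight", [0.0, 0.7])
    def test_dual_cross_entropy_gradient(self, f64, fp_weight):
        rng = np.random.default_rng(4)
        scores = Var(rng.standard_normal((3, 3, 3, 2)), requires_grad=True)
        target = rng.integers(0, 3, (3, 3, 2))
        loss = dual_cross_entropy(scores, target, fp_weight=fp_weight)
        loss.backward()
        num = numeric_grad(
            lambda: float(dual_cross_entropy(scores, target, fp_weight=fp_weight).data),
            scores.data)
        assert np.allclose(scores.grad, num, atol=1e-5)

    def test_binary_and_dice_loss_gradients(self, f64):
        rng = np.random.default_rng(5)
        scores = Var(rng.standard_normal((2, 3, 3, 2)), requires_grad=True)
        target_ml = (rng.random((2, 3, 3, 2)) < 0.4).astype(float)
        loss = sigmoid_bce(scores, target_ml)
        loss.backward()
        num = numeric_grad(lambda: float(sigmoid_bce(scores, target_ml).data),
                           scores.data)
        assert np.allclose(scores.grad, num, atol=1e-5)

        scores2 = Var(rng.standard_normal((2, 3, 3, 2)), requires_grad=True)
        target_b = (rng.random((3, 3, 2)) < 0.5).astype(float)
        dice_loss(scores2, target_b).backward()
        num2 = numeric_grad(lambda: float(dice_loss(scores2, target_b).data),
                            scores2.data)
        assert np.allclose(scores2.grad, num2, atol=1e-5)


class TestLossValues:
    def test_fp_weight_zero_equals_direct_cross_entropy(self, rng):
        scores = Var(rng.standard_normal((4, 4, 4, 2)).astype(np.float32))
        target = rng.integers(0, 4, (4, 4, 2))
        loss = float(dual_cross_entropy(scores, target, fp_weight=0.0).data)
        p = softmax(scores.data.reshape(4, -1).astype(np.float64))
        direct = -np.log(p[target.reshape(-1), np.arange(target.size)]).mean()
        assert loss == pytest.approx(direct, rel=1e-6)

    def test_uniform_two_class_prediction_gives_log_two(self):
        scores = Var(np.zeros((2, 2, 2, 2)))
        target = np.zeros((2, 2, 2), dtype=int)
        loss = float(dual_cross_entropy(scores, target, fp_weight=0.0).data)
        assert loss == pytest.approx(np.log(2), rel=1e-6)

    def test_confident_correct_prediction_has_near_zero_loss(self):
        target = np.array([[[0, 1]]])
        scores = np.zeros((2, 1, 1, 2))
        scores[0, 0, 0, 0] = 30.0
        scores[1, 0, 0, 1] = 30.0
        loss = float(dual_cross_entropy(Var(scores), target, fp_weight=1.0).data)
        assert 0.0 <= loss < 1e-5

    def test_loss_finite_for_extreme_scores(self):
        scores = Var(np.full((2, 2, 2, 2), 1e4))
        target = np.ones((2, 2, 2), dtype=int)
        assert np.isfinite(float(dual_cross_entropy(Var(scores.data), target).data))

    def test_shape_and_label_validation(self):
        scores = Var(np.zeros((2, 2, 2, 2)))
        with pytest.raises(ValueError):
            dual_cross_entropy(scores, np.zeros((3, 2, 2), dtype=int))
        with pytest.raises(ValueError):
            dual_cross_entropy(scores, np.full((2, 2, 2), 5))


TINY = dict(layers_per_block=(1, 1), growth_rate=2, n_transitions=1,
            pool_factors=((2, 2, 2),), first_channels=4)


class TestNetwork:
    @pytest.mark.parametrize("config,shape", [
        (NetworkConfig(layers_per_block=(1, 1, 1), growth_rate=2, n_transitions=2,
                       out_channels=2, first_channels=4), (16, 16, 8)),
        (NetworkConfig(out_channels=3, **TINY), (8, 6, 4)),
        (NetworkConfig(out_channels=5, mode="multilabel", **TINY), (8, 8, 2)),
    ])
    def test_output_spatial_shape_matches_input(self, config, shape, rng):
        net = build_network(config, seed=0)
        out = net.forward(rng.standard_normal(shape).astype(np.float32))
        assert out.data.shape == (config.out_channels,) + shape

    def test_parameter_count_increases_with_growth_rate(self):
        small = build_network(NetworkConfig(out_channels=2, **{**TINY, "growth_rate": 2}))
        large = build_network(NetworkConfig(out_channels=2, **{**TINY, "growth_rate": 4}))
        assert large.n_parameters() > small.n_parameters()

    def test_seeded_builds_are_identical(self):
        cfg = NetworkConfig(out_channels=2, **TINY)
        a, b = build_network(cfg, seed=3), build_network(cfg, seed=3)
        for k in a.parameters():
            assert np.array_equal(a.params[k].data, b.params[k].data)
        c = build_network(cfg, seed=4)
        assert any(not np.array_equal(a.params[k].data, c.params[k].data)
                   for k in a.parameters())

    def test_indivisible_input_shape_rejected(self, rng):
        net = build_network(NetworkConfig(out_channels=2, **TINY))
        with pytest.raises(ValueError, match="divisible"):
            net.forward(rng.standard_normal((7, 8, 8)).astype(np.float32))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(layers_per_block=(1, 1), n_transitions=2)
        with pytest.raises(ValueError):
            NetworkConfig(growth_rate=0, layers_per_block=(1,), n_transitions=0)

    def test_predict_probabilities_normalized_and_deterministic(self, rng):
        net = build_network(NetworkConfig(out_channels=3, **TINY), seed=1)
        x = rng.standard_normal((8, 8, 4)).astype(np.float32)
        probs, labels = net.predict(x)
        assert np.allclose(probs.sum(axis=0), 1.0, atol=1e-6)
        assert set(np.unique(labels)) <= {0, 1, 2}
        probs2, labels2 = net.predict(x)
        assert np.array_equal(probs, probs2) and np.array_equal(labels, labels2)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        net = build_network(NetworkConfig(out_channels=2, **TINY), seed=5)
        x = rng.standard_normal((8, 8, 4)).astype(np.float32)
        net.save(tmp_path / "ckpt.npz")
        back = FCDenseNet3D.load(tmp_path / "ckpt.npz")
        assert back.config == net.config
        assert np.array_equal(back.predict(x)[0], net.predict(x)[0])


class TestTraining:
    def _sample(self, rng, shape=(8, 8, 4)):
        target = np.zeros(shape, dtype=np.int64)
        target[2:6, 2:6, 1:3] = 1
        img = rng.normal(0, 0.1, shape).astype(np.float32) + 0.8 * target
        return img, target

    def test_zero_epochs_returns_network_unchanged(self, rng):
        net = build_network(NetworkConfig(out_channels=2, **TINY), seed=0)
        before = {k: v.copy() for k, v in net.state_dict().items()}
        _, history = train(net, [self._sample(rng)], TrainConfig(seed=0), epochs=0)
        assert history == []
        for k, v in net.state_dict().items():
            assert np.array_equal(v, before[k])

    def test_same_seed_replays_identical_loss_history(self, rng):
        cfg = NetworkConfig(out_channels=2, **TINY)
        sample = self._sample(rng)
        _, h1 = train(build_network(cfg, seed=2), [sample],
                      TrainConfig(seed=9, learning_rate=1e-3), epochs=5)
        _, h2 = train(build_network(cfg, seed=2), [sample],
                      TrainConfig(seed=9, learning_rate=1e-3), epochs=5)
        assert h1 == h2

    def test_overfit_smoke_reduces_loss(self, rng):
        net = build_network(NetworkConfig(out_channels=2, **TINY), seed=0)
        _, history = train(net, [self._sample(rng)],
                           TrainConfig(seed=0, learning_rate=2e-3, fp_weight=0.0),
                           epochs=30)
        assert history[-1] < history[0]
        assert np.mean(np.diff(history)) < 0

    def test_checkpoints_and_log_written(self, tmp_path, rng):
        net = build_network(NetworkConfig(out_channels=2, **TINY), seed=0)
        train(net, [self._sample(rng)], TrainConfig(seed=0), epochs=3,
              checkpoint_dir=tmp_path)
        assert (tmp_path / "best.npz").exists()
        assert (tmp_path / "last.npz").exists()
        assert (tmp_path / "train_log.csv").read_text().startswith("epoch,loss")

    def test_empty_sample_list_rejected(self):
        net = build_network(NetworkConfig(out_channels=2, **TINY), seed=0)
        with pytest.raises(ValueError):
            train(net, [], TrainConfig(), epochs=1)
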