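"""Network architecture, splitting, training behavior, inference contracts."""

import numpy as np
import pytest

from vmono import physics as P
from vmono.network import (NetConfig, TrainedModel, build_network, desk_config,
                           predict, predict_images, split_dataset,
                           split_indices, train)
from vmono.phantoms import make_cylinder_phantom
from vmono.projector import Geometry, ProjectionSet, project_mono


def _conv_params(cin, cout, k=3):
    return cin * cout * k * k + cout


def _expected_params(depth, base, in_ch=1, out_ch=1):
    f = [base * 2 ** i for i in range(depth)]
    total = 0
    for i in range(depth):
        cin = in_ch if i == 0 else f[i - 1]
        total += _conv_params(cin, f[i]) + _conv_params(f[i], f[i])
    for i in range(depth - 1):
        total += _conv_params(f[i + 1] + f[i], f[i]) + _conv_params(f[i], f[i])
    total += _conv_params(f[0], out_ch, 1)
    return total


class TestArchitecture:
    def test_full_scale_bottleneck_is_1024(self):
        cfg = NetConfig(depth=7, base_features=16)
        assert cfg.bottleneck_features == 1024
        net = build_network(cfg)
        # deepest encoder block's second conv outputs 1024 feature maps
        assert net.enc[-1].layers[2].W.shape[0] == 1024

    def test_small_config_bottleneck(self):
        assert NetConfig(depth=4, base_features=8).bottleneck_features == 64

    @pytest.mark.parametrize("depth,base", [(2, 4), (3, 8)])
    def test_parameter_count_formula(self, depth, base):
        net = build_network(NetConfig(depth=depth, base_features=base))
        assert net.num_params == _expected_params(depth, base)

    def test_output_shape_equals_input_shape(self):
        net = build_network(NetConfig(depth=3, base_features=4, seed=2))
        x = np.random.default_rng(0).normal(size=(2, 1, 16, 24)).astype(np.float32)
        assert net.forward(x).shape == x.shape

    def test_indivisible_input_rejected_with_padding_hint(self):
        net = build_network(NetConfig(depth=4, base_features=4))
        x = np.zeros((1, 1, 60, 64), np.float32)
        with pytest.raises(ValueError, match="64"):
            net.forward(x)

    def test_zero_init_head_predicts_zero(self):
        net = build_network(NetConfig(depth=3, base_features=4, seed=1,
                                      final_zero_init=True))
        x = np.random.default_rng(0).uniform(0, 2, (1, 1, 16, 16)).astype(np.float32)
        assert np.abs(net.forward(x)).max() == 0.0


class TestSplit:
    def test_full_scale_split(self):
        tr, te = split_indices(1890, 0.8, seed=0)
        assert (len(tr), len(te)) == (1512, 378)

    def test_small_split(self):
        tr, te = split_indices(10, 0.8, seed=0)
        assert (len(tr), len(te)) == (8, 2)

    def test_split_disjoint_and_deterministic(self):
        tr1, te1 = split_indices(100, 0.8, seed=5)
        tr2, te2 = split_indices(100, 0.8, seed=5)
        np.testing.assert_array_equal(tr1, tr2)
        np.testing.assert_array_equal(te1, te2)
        assert set(tr1).isdisjoint(te1)
        assert len(set(tr1) | set(te1)) == 100

    def test_split_dataset_sequences(self):
        tr, te = split_dataset(list(range(10)), 0.8, seed=1)
        assert len(tr) == 8 and len(te) == 2
        assert set(tr).isdisjoint(te)

    def test_invalid_split_rejected(self):
        with pytest.raises(ValueError):
            split_indices(0, 0.8)
        with pytest.raises(ValueError):
            split_indices(10, 1.5)


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        cfg = NetConfig(depth=3, base_features=2, seed=0, final_zero_init=False)
        net = build_network(cfg)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 1, 8, 8)).astype(np.float32)
        y = rng.normal(size=(2, 1, 8, 8)).astype(np.float32)
        resid = net.forward(x) - y
        net.zero_grad()
        net.backward(np.sign(resid).astype(np.float32) / resid.size)
        params = net.params()
        for pi in (0, 5, len(params) - 2, len(params) - 1):
            w, g = params[pi]
            flat, gflat = w.ravel(), g.ravel()
            for k in (0, flat.size // 2):
                eps = 1e-3
                old = flat[k]
                flat[k] = old + eps
                lp = float(np.abs(net.forward(x) - y).mean())
                flat[k] = old - eps
                lm = float(np.abs(net.forward(x) - y).mean())
                flat[k] = old
                num = (lp - lm) / (2 * eps)
                assert gflat[k] == pytest.approx(num, rel=3e-2, abs=3e-4)


def _mono_image_corpus(n=24, size=32):
    """Small stack of analytic monoenergetic cylinder projections."""
    g = Geometry.desk(size, 1.0)
    rng = np.random.default_rng(0)
    imgs = []
    for i in range(n):
        d = rng.uniform(4.0, 9.0)
        ph = make_cylinder_phantom(d, 12.0, P.tissue("water"), (0, 0, 1),
                                   shape=(32, 32, 32),
                                   voxel_size=(0.45, 0.45, 0.45))
        imgs.append(project_mono(ph, g, 35.0, [float(i * 7 % 360)]).images[0])
    return np.asarray(imgs)[:, None]


class TestTraining:
    def test_identity_task_converges(self):
        """mono->mono training beats the untrained model by >= 10x."""
        y = _mono_image_corpus()
        cfg = NetConfig(depth=3, base_features=8, learning_rate=1e-3,
                        batch_size=8, epochs=50, seed=3)
        net = build_network(cfg)
        untrained_mae = float(np.abs(net.forward(y) - y).mean())  # zero head
        trained = train(net, y, y, cfg, y[:6], y[:6])
        assert trained.history["val_mae"][-1] < untrained_mae / 10

    def test_zero_learning_rate_keeps_weights(self):
        y = np.random.default_rng(0).uniform(0, 1, (8, 1, 8, 8)).astype(np.float32)
        cfg = NetConfig(depth=2, base_features=4, learning_rate=0.0,
                        batch_size=4, epochs=3, seed=0, final_zero_init=False)
        net = build_network(cfg)
        before = net.get_weights()
        trained = train(net, y, y, cfg, y, y)
        after = net.get_weights()
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a)
        # flat loss curve (up to batch-order float summation noise)
        h = trained.history["train_mae"]
        np.testing.assert_allclose(h, h[0], rtol=1e-6)

    def test_history_and_provenance_recorded(self):
        y = np.random.default_rng(0).uniform(0, 1, (6, 1, 8, 8)).astype(np.float32)
        cfg = NetConfig(depth=2, base_features=2, learning_rate=1e-4,
                        batch_size=3, epochs=4, seed=1)
        trained = train(build_network(cfg), y, y, cfg, y, y)
        assert trained.epochs_run == 4
        assert len(trained.history["val_mae"]) == 4
        assert trained.provenance["n_train"] == 6
        assert "dataset_hash" in trained.provenance

    def test_shape_mismatch_rejected(self):
        cfg = NetConfig(depth=2, base_features=2, epochs=1)
        x = np.zeros((4, 1, 8, 8), np.float32)
        with pytest.raises(ValueError):
            train(build_network(cfg), x, x[:, :, :4], cfg)

    def test_nonfinite_loss_aborts(self):
        cfg = NetConfig(depth=2, base_features=2, epochs=1,
                        final_zero_init=False)
        x = np.full((4, 1, 8, 8), np.inf, np.float32)
        with pytest.raises(RuntimeError, match="non-finite"):
            train(build_network(cfg), x, x, cfg)


class TestInference:
    def _tiny_trained(self):
        cfg = NetConfig(depth=2, base_features=2, epochs=1, seed=0,
                        learning_rate=1e-4, batch_size=2)
        y = np.random.default_rng(0).uniform(0, 1, (4, 1, 8, 8)).astype(np.float32)
        return train(build_network(cfg), y, y, cfg, y, y)

    def test_predict_deterministic_and_pure(self):
        trained = self._tiny_trained()
        x = np.random.default_rng(1).uniform(0, 1, (3, 16, 16)).astype(np.float32)
        x_copy = x.copy()
        a = predict_images(trained, x)
        b = predict_images(trained, x)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(x, x_copy)

    def test_predict_pads_odd_sizes(self):
        trained = self._tiny_trained()
        x = np.random.default_rng(2).uniform(0, 1, (2, 15, 13)).astype(np.float32)
        out = predict_images(trained, x)
        assert out.shape == x.shape

    def test_predict_warns_on_non_poly_kind(self):
        trained = self._tiny_trained()
        g = Geometry.desk(16, 1.0)
        proj = ProjectionSet(np.zeros((1, 16, 16), np.float32), [0.0], g, "mono")
        with pytest.warns(UserWarning, match="mono"):
            out = predict(trained, proj)
        assert out.kind == "predicted-mono"
        assert out.geometry is proj.geometry

    def test_predicted_set_carries_provenance(self):
        trained = self._tiny_trained()
        g = Geometry.desk(16, 1.0)
        proj = ProjectionSet(np.zeros((2, 16, 16), np.float32), [0.0, 10.0],
                             g, "poly")
        out = predict(trained, proj)
        assert out.meta["model"]["epochs_run"] == 1
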