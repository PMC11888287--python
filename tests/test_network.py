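"""Network engine: scaling, schedule, forward semantics, gradients, capacity."""

import numpy as np
import pytest

from lipoinfer import ConvNet, NetworkConfig, ParamScaler, lr_schedule, mse_loss
from lipoinfer.features import n_rows


class TestParamScaler:
    def test_endpoints_and_midpoint(self):
        s = ParamScaler([0.0, 10.0], [2.0, 30.0])
        assert np.allclose(s.scale([0.0, 10.0]), [0.0, 0.0])
        assert np.allclose(s.scale([2.0, 30.0]), [1.0, 1.0])
        assert np.allclose(s.scale([1.0, 20.0]), [0.5, 0.5])

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        s = ParamScaler(rng.random(4), 1 + rng.random(4))
        x = rng.random((20, 4))
        assert np.allclose(s.unscale(s.scale(x)), x, atol=1e-12)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            ParamScaler([1.0], [1.0])


class TestLrSchedule:
    def test_peak_and_start(self):
        assert lr_schedule(0, 1e-3, 10, 100) == 0.0
        assert lr_schedule(10, 1e-3, 10, 100) == pytest.approx(1e-3)

    def test_monotone_decay_after_peak(self):
        lrs = [lr_schedule(e, 1e-3, 10, 100) for e in range(10, 101)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        assert lrs[-1] == pytest.approx(1e-5)


class TestLoss:
    def test_trivial_values(self):
        z, o = np.zeros((3, 4)), np.ones((3, 4))
        assert mse_loss(o, o)[0] == 0.0
        assert mse_loss(z, o)[0] == 1.0

    def test_matches_hand_mean_of_squares(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((5, 3)), rng.random((5, 3))
        loss, grad = mse_loss(a, b)
        assert loss == pytest.approx(np.mean((a - b) ** 2))
        assert np.allclose(grad, 2 * (a - b) / a.size)


def _net(layout, n_times=28, npara=4, dtype=np.float32, **kw):
    cfg = NetworkConfig(layout, n_rows(layout), n_times, npara, **kw)
    return ConvNet(cfg, dtype=dtype)


class TestForward:
    def test_scaled_tanh_outputs_open_unit_interval(self):
        net = _net("recip_time")
        y = net.forward(np.random.default_rng(0).random((8, 18, 28)))
        assert np.all((y > 0) & (y < 1))

    def test_relu_outputs_nonnegative(self):
        net = _net("none", final_activation="relu")
        y = net.forward(np.random.default_rng(0).random((8, 12, 28)))
        assert np.all(y >= 0)

    def test_scaled_tanh_at_zero_preactivation(self):
        net = _net("none")
        # zero final weights and bias -> pre-activation 0 -> output 0.5
        final = net.layers[-2]
        final.W[...] = 0.0
        final.b[...] = 0.0
        y = net.forward(np.random.default_rng(0).random((4, 12, 28)))
        assert np.allclose(y, 0.5)

    def test_deterministic_given_weights(self):
        net = _net("mutual_recip")
        X = np.random.default_rng(2).random((6, 24, 28))
        assert np.array_equal(net.forward(X), net.forward(X))

    def test_shape_mismatch_named_error(self):
        net = _net("recip_time")
        with pytest.raises(ValueError, match="recip_time"):
            net.forward(np.zeros((4, 12, 28)))

    def test_first_layer_kernel_is_finite_difference_stencil(self):
        """A hand-set [[+1,-1],[+1,-1]]/(2 dt) kernel over the (t, G) row pair
        reproduces the finite-difference derivative dG/dt."""
        dt = 2.0
        t = np.arange(0, 56, dt, dtype=float)
        rng = np.random.default_rng(3)
        G = 100 + 30 * rng.random(len(t))
        net = _net("none", n_times=len(t))
        conv1 = net.layers[0]
        conv1.W[...] = 0.0
        conv1.b[...] = 0.0
        # channel 0 reads rows (0, 1) = (t, G):
        # out = (w00 t_j + w01 t_{j+1}) + (w10 G_j + w11 G_{j+1})
        conv1.W[0, 0] = np.array([[0.0, 0.0], [-1.0, 1.0]]) / dt
        X = np.zeros((1, 12, len(t)), dtype=np.float32)
        X[0, 0], X[0, 1] = t, G
        out = conv1.forward(X[:, None].astype(np.float32))
        fd = np.diff(G) / dt
        assert np.allclose(out[0, 0, 0], fd, atol=1e-4)


class TestGradients:
    @pytest.mark.parametrize("layout", ["none", "recip_time"])
    def test_analytic_gradients_match_central_differences(self, layout):
        rng = np.random.default_rng(7)
        net = _net(layout, npara=3, dtype=np.float64,
                   conv_channels=(2, 3), dense_width=8, concat_channels=1)
        # randomize all weights (incl. biases) away from ReLU kinks
        net.set_weights([0.3 * rng.standard_normal(w.shape)
                         for w, _ in net.parameters()])
        X = rng.random((4, n_rows(layout), 28))
        y = rng.random((4, 3))

        def loss_at():
            return mse_loss(net.forward(X), y)[0]

        net.zero_grad()
        pred = net.forward(X)
        _, d = mse_loss(pred, y)
        net.backward(d)
        for w, g in net.parameters():
            for idx in [tuple(rng.integers(0, s) for s in w.shape)
                        for _ in range(4)]:
                eps, orig = 1e-6, w[idx]
                w[idx] = orig + eps
                lp = loss_at()
                w[idx] = orig - eps
                lm = loss_at()
                w[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - g[idx]) <= 1e-4 * max(1.0, abs(fd)), (w.shape, idx)


class TestCapacity:
    def test_overfits_small_dataset(self):
        """The default architecture can drive training MSE to ~0 on a tiny
        dataset (sanity check that optimization and capacity suffice)."""
        from lipoinfer import CNNParameterRegressor
        rng = np.random.default_rng(5)
        X = rng.random((200, 12, 28))
        y = rng.random((200, 3))
        model = CNNParameterRegressor(layout="none", model_id="2d",
                                      epochs=2000, batch_size=200,
                                      max_lr=3e-3, seed=0)
        model.fit(X, y, param_names=["a", "b", "c"])
        assert min(model.loss_curve_) < 1e-4


class TestSerialization:
    def test_weight_round_trip(self):
        net = _net("recip_time")
        X = np.random.default_rng(0).random((3, 18, 28))
        ref = net.forward(X)
        clone = _net("recip_time", seed=1)
        clone = ConvNet(net.config)
        clone.set_weights(net.get_weights())
        assert np.array_equal(clone.forward(X), ref)
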