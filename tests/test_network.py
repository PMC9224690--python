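"""Architecture contract, gradient correctness, and training behaviour."""

import numpy as np
import pytest

from camrad.nn.layers import BatchNorm2d, BilinearResize, Conv2d, MaxPool2d, ReLU
from camrad.nn.resnet import build_model, softmax
from camrad.nn.training import (
    EPOCH_GRID,
    LR_GRID,
    TrainConfig,
    broadcast_label,
    predict_patient,
    train,
)

rng = np.random.default_rng(0)


class TestArchitecture:
    def test_shapes_m8(self):
        model = build_model(8, seed=0)
        x = rng.standard_normal((1, 224, 224, 1)).astype(np.float32)
        feat = model.forward_trunk(x, train=False)
        assert feat.shape == (1, 7, 7, 512)
        up = model.upsample.forward(feat)
        assert up.shape == (1, 86, 8, 512)
        logits = model.head_conv.forward(up, train=False)
        assert logits.shape == (1, 86, 8, 2)

    @pytest.mark.parametrize("m", [1, 3, 8])
    def test_head_matches_grid_width(self, m):
        model = build_model(m, seed=0)
        x = rng.standard_normal((2, 224, 224, 1)).astype(np.float32)
        assert model.forward(x, train=False).shape == (2, 86, m, 2)

    def test_m_out_of_range(self):
        for m in (0, 9):
            with pytest.raises(ValueError):
                build_model(m)

    def test_input_size_enforced(self):
        model = build_model(2, seed=0)
        with pytest.raises(ValueError, match="224"):
            model.forward(np.zeros((1, 100, 100, 1), dtype=np.float32))

    def test_each_residual_unit_has_two_3x3_convs(self):
        model = build_model(4, seed=0)
        for stage in model.stages:
            for block in stage:
                assert (block.conv1.kh, block.conv1.kw) == (3, 3)
                assert (block.conv2.kh, block.conv2.kw) == (3, 3)

    def test_parameter_count_regression(self):
        """Canonical 18-layer trunk adapted to 1 input channel.

        The standard trunk (conv + batch-norm parameters, no fc) has
        11,176,512 parameters; a single-channel stem removes 6,272 of the
        first convolution's weights -> 11,170,240.  The cam head adds a
        1x1x512x2 conv + bias = 1,026.
        """
        model = build_model(8, seed=0)
        assert model.n_trunk_parameters == 11_170_240
        assert model.n_parameters == 11_170_240 + 1_026

    def test_fresh_model_softmax_normalized(self):
        model = build_model(5, seed=3)
        x = rng.standard_normal((2, 224, 224, 1)).astype(np.float32)
        p = softmax(model.forward(x, train=False))
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-6)

    def test_classic_head_scalar_logits(self):
        model = build_model(8, head="classic", seed=0)
        x = rng.standard_normal((2, 224, 224, 1)).astype(np.float32)
        assert model.forward(x, train=False).shape == (2, 2)


class TestBroadcastLabel:
    def test_all_ones_m8(self):
        lbl = broadcast_label(1, 8)
        assert lbl.shape == (86, 8, 1)
        assert (lbl == 1).all()

    def test_all_zeros(self):
        assert (broadcast_label(0, 3) == 0).all()

    def test_cell_count_m2(self):
        assert broadcast_label(1, 2).sum() == 172

    def test_binary_only(self):
        with pytest.raises(ValueError):
            broadcast_label(2, 4)


class TestGradients:
    """Finite-difference checks of each layer's backward pass."""

    @staticmethod
    def _check(layer, x, eps=1e-2, tol=2e-2, params=True):
        w_out = np.random.default_rng(5).standard_normal(
            layer.forward(x.copy(), train=True).shape
        ).astype(np.float32)

        def loss_of(xv):
            return float((layer.forward(xv, train=True) * w_out).sum())

        layer.forward(x.copy(), train=True)
        dx = layer.backward(w_out.copy())
        # input gradient at a few positions
        idx = [tuple(np.random.default_rng(i).integers(0, s) for s in x.shape)
               for i in range(6)]
        for pos in idx:
            xp = x.copy(); xp[pos] += eps
            xm = x.copy(); xm[pos] -= eps
            num = (loss_of(xp) - loss_of(xm)) / (2 * eps)
            assert dx[pos] == pytest.approx(num, abs=max(0.05, tol * abs(num)))
        if not params:
            return
        for name, p in layer.params():
            layer.forward(x.copy(), train=True)
            p.grad[:] = 0
            layer.backward(w_out.copy())
            g = p.grad.copy()
            flat = p.value.reshape(-1)
            for k in np.random.default_rng(9).integers(0, flat.size, 4):
                orig = flat[k]
                flat[k] = orig + eps
                lp = loss_of(x.copy())
                flat[k] = orig - eps
                lm = loss_of(x.copy())
                flat[k] = orig
                num = (lp - lm) / (2 * eps)
                assert g.reshape(-1)[k] == pytest.approx(
                    num, abs=max(0.05, tol * abs(num))), name

    def test_conv(self):
        r = np.random.default_rng(1)
        layer = Conv2d(3, 3, 2, 3, stride=1, pad=1, rng=r)
        self._check(layer, r.standard_normal((2, 6, 6, 2)).astype(np.float32))

    def test_conv_strided_im2col_path(self):
        r = np.random.default_rng(2)
        layer = Conv2d(3, 3, 1, 4, stride=2, pad=1, rng=r)  # narrow: im2col
        self._check(layer, r.standard_normal((2, 8, 8, 1)).astype(np.float32))

    def test_batchnorm(self):
        r = np.random.default_rng(3)
        layer = BatchNorm2d(3)
        self._check(layer, r.standard_normal((3, 4, 4, 3)).astype(np.float32))

    def test_bilinear_resize(self):
        r = np.random.default_rng(4)
        layer = BilinearResize((7, 7), (20, 5))
        self._check(layer, r.standard_normal((2, 7, 7, 3)).astype(np.float32),
                    params=False)

    def test_maxpool(self):
        r = np.random.default_rng(6)
        # well-separated values keep the argmax stable under the probe eps
        x = (10 * r.standard_normal((2, 8, 8, 2))).astype(np.float32)
        self._check(MaxPool2d(3, 2, 1), x, params=False)

    def test_relu(self):
        r = np.random.default_rng(7)
        x = (r.standard_normal((2, 5, 5, 2)) + 0.5).astype(np.float32)
        x[np.abs(x) < 0.1] = 0.5  # keep away from the kink
        self._check(ReLU(), x, params=False)


class TestTraining:
    def _banded_set(self, n=8):
        y = np.array([0, 1] * (n // 2))
        X = rng.standard_normal((n, 224, 224)).astype(np.float32) * 0.3
        X[y == 1, 60:80, :] += 1.5
        return X, y

    def test_config_defaults_match_published_values(self):
        cfg = TrainConfig()
        assert cfg.momentum == 0.9
        assert cfg.weight_decay == 0.0004
        assert cfg.batch_size == 32
        assert cfg.learning_rate in LR_GRID
        assert cfg.epochs in EPOCH_GRID
        assert LR_GRID == (0.1, 0.01, 0.001)
        assert EPOCH_GRID == (200, 400, 600)

    def test_loss_decreases_on_separable_data(self):
        X, y = self._banded_set(8)
        model = build_model(8, seed=1)
        hist = train(model, X, y,
                     TrainConfig(learning_rate=0.01, epochs=5, batch_size=2,
                                 seed=1))
        assert len(hist) == 5
        assert hist[-1] < hist[0]

    def test_same_seed_identical_histories(self):
        X, y = self._banded_set(4)
        cfg = TrainConfig(learning_rate=0.01, epochs=2, batch_size=2, seed=7)
        h1 = train(build_model(8, seed=2), X, y, cfg)
        h2 = train(build_model(8, seed=2), X, y, cfg)
        assert h1 == h2

    def test_overfit_single_example_per_cell(self):
        X, y = self._banded_set(2)
        model = build_model(8, seed=3)
        train(model, X[1:2], y[1:2],
              TrainConfig(learning_rate=0.01, epochs=25, batch_size=1, seed=0))
        probs = model.cell_probabilities(X[1:2])[0]
        assert (probs.argmax(axis=-1) == 1).mean() == 1.0

    def test_divergence_aborts_with_advice(self):
        X, y = self._banded_set(2)
        model = build_model(8, seed=0)
        with pytest.raises(RuntimeError, match="learning rate"), np.errstate(
            all="ignore"
        ):
            train(model, X, y,
                  TrainConfig(learning_rate=1e12, epochs=3, batch_size=2,
                              seed=0))


class TestPredictPatient:
    def test_range_and_batch_invariance(self):
        model = build_model(4, seed=5)
        X = rng.standard_normal((3, 224, 224)).astype(np.float32)
        batch = predict_patient(model, X)
        assert ((batch >= 0) & (batch <= 1)).all()
        alone = predict_patient(model, X[1])
        assert alone == pytest.approx(float(batch[1]), abs=1e-6)

    def test_symmetric_logits_score_half(self):
        model = build_model(2, seed=0)
        model.head_conv.weight.value[:] = 0
        model.head_conv.bias.value[:] = 0
        x = rng.standard_normal((224, 224)).astype(np.float32)
        assert predict_patient(model, x) == pytest.approx(0.5)

    def test_saturated_head_scores_one(self):
        model = build_model(2, seed=0)
        model.head_conv.weight.value[:] = 0
        model.head_conv.bias.value[:] = [-20.0, 20.0]
        x = rng.standard_normal((224, 224)).astype(np.float32)
        assert predict_patient(model, x) == pytest.approx(1.0, abs=1e-6)
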