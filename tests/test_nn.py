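"""Sequence model: shapes, gradients, causality, masking, training loop."""

import numpy as np
import pytest

from vegmem import nn


def tiny_cfg(**kw):
    base = dict(n_features=3, fc_layers=2, fc_width=6, dropout=0.0,
                lstm_hidden=5, batch_size=4, max_epochs=5, patience=2, seed=7)
    base.update(kw)
    return nn.ModelConfig(**base)


class TestBuild:
    def test_shapes_default_family(self):
        cfg = nn.ModelConfig(n_features=27, max_epochs=1)
        m = nn.build_model(cfg)
        x = np.zeros((2, 10, 27))
        assert m.forward(x).shape == (2, 10)

    def test_feature_mismatch(self):
        m = nn.build_model(tiny_cfg())
        with pytest.raises(ValueError):
            m.forward(np.zeros((1, 5, 4)))

    def test_no_encoder_variant(self):
        m = nn.build_model(tiny_cfg(fc_layers=0))
        assert "enc_W0" not in m.params
        assert m.forward(np.zeros((1, 4, 3))).shape == (1, 4)

    def test_seed_determinism(self):
        a = nn.build_model(tiny_cfg())
        b = nn.build_model(tiny_cfg())
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])


class TestGradients:
    def test_numerical_gradient_check(self, rng):
        cfg = tiny_cfg(lstm_layers=2)
        m = nn.build_model(cfg)
        x = rng.normal(size=(2, 6, 3))
        y = rng.normal(size=(2, 6))
        mask = rng.random((2, 6)) < 0.6
        _, grads = m.loss_and_grads(x, y, mask, rng)

        def loss():
            r = np.where(mask, m.forward(x) - y, 0.0)
            return np.sum(r * r) / mask.sum()

        eps = 1e-6
        for k, p in m.params.items():
            flat_idx = rng.choice(p.size, size=min(4, p.size), replace=False)
            for fi in flat_idx:
                ij = np.unravel_index(fi, p.shape)
                old = p[ij]
                p[ij] = old + eps
                fp = loss()
                p[ij] = old - eps
                fm = loss()
                p[ij] = old
                num = (fp - fm) / (2 * eps)
                assert grads[k][ij] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_masked_steps_zero_gradient(self, rng):
        m = nn.build_model(tiny_cfg())
        x = rng.normal(size=(1, 8, 3))
        y = rng.normal(size=(1, 8))
        mask = np.ones((1, 8), bool)
        mask[0, 3] = False
        l1, g1 = m.loss_and_grads(x, y, mask, rng)
        y2 = y.copy()
        y2[0, 3] = 99.0  # perturb a masked target
        l2, g2 = m.loss_and_grads(x, y2, mask, rng)
        assert l1 == l2
        for k in g1:
            np.testing.assert_array_equal(g1[k], g2[k])

    def test_empty_mask_error(self, rng):
        m = nn.build_model(tiny_cfg())
        with pytest.raises(ValueError):
            m.loss_and_grads(np.zeros((1, 4, 3)), np.zeros((1, 4)),
                             np.zeros((1, 4), bool), rng)


class TestCausality:
    def test_future_inputs_do_not_change_past(self, rng):
        m = nn.build_model(tiny_cfg())
        x = rng.normal(size=(2, 9, 3))
        base = m.forward(x)
        x2 = x.copy()
        x2[:, 5:] += 100.0
        pert = m.forward(x2)
        np.testing.assert_array_equal(base[:, :5], pert[:, :5])
        assert not np.allclose(base[:, 5:], pert[:, 5:])


class TestTrain:
    def test_learns_constant(self, rng):
        cfg = tiny_cfg(max_epochs=200, patience=50, learning_rate=0.02)
        m = nn.build_model(cfg)
        x = rng.normal(size=(4, 10, 3))
        y = np.full((4, 10), 0.7)
        mask = np.ones((4, 10), bool)
        nn.train(m, [(x, y, mask)], [(x, y, mask)], cfg)
        assert np.abs(m.forward(x) - 0.7).max() < 0.05

    def test_learns_linear_function_of_inputs(self, rng):
        cfg = tiny_cfg(fc_layers=1, fc_width=12, lstm_hidden=12,
                       max_epochs=300, patience=60, learning_rate=0.02, seed=1)
        m = nn.build_model(cfg)
        w = np.array([0.5, -1.0, 0.25])
        x = rng.normal(size=(12, 20, 3))
        y = x @ w
        tr = [(x[:8], y[:8], np.ones((8, 20), bool))]
        va = [(x[8:], y[8:], np.ones((4, 20), bool))]
        nn.train(m, tr, va, cfg)
        pred = m.forward(x[8:])
        r = np.corrcoef(pred.ravel(), y[8:].ravel())[0, 1]
        assert r ** 2 > 0.9

    def test_patience_zero_stops_first_plateau(self, rng):
        cfg = tiny_cfg(max_epochs=50, patience=0, learning_rate=1e-300)
        m = nn.build_model(cfg)
        x = rng.normal(size=(2, 5, 3))
        y = rng.normal(size=(2, 5))
        mask = np.ones((2, 5), bool)
        nn.train(m, [(x, y, mask)], [(x, y, mask)], cfg)
        # negligible lr -> val never improves after the first epoch -> stop at epoch 2
        assert len(m.history) == 2

    def test_best_params_restored(self, rng):
        cfg = tiny_cfg(max_epochs=30, patience=3, learning_rate=0.05)
        m = nn.build_model(cfg)
        x = rng.normal(size=(4, 8, 3))
        y = rng.normal(size=(4, 8))
        mask = np.ones((4, 8), bool)
        nn.train(m, [(x, y, mask)], [(x, y, mask)], cfg)
        best = min(h["val_loss"] for h in m.history)
        r = np.where(mask, m.forward(x) - y, 0.0)
        assert np.sum(r * r) / mask.sum() == pytest.approx(best, rel=1e-6)


class TestPredict:
    def test_warmup_arithmetic(self):
        m = nn.build_model(tiny_cfg())
        x = np.zeros((216, 3))  # a 9-year fold at 24 steps/year
        pred, ok = nn.predict(m, x, warmup_steps=24)
        assert pred.shape == (216,)
        assert ok.sum() == 192

    def test_no_warmup_all_evaluable(self):
        m = nn.build_model(tiny_cfg())
        _, ok = nn.predict(m, np.zeros((2, 5, 3)), warmup_steps=0)
        assert ok.all()

    def test_deterministic_with_dropout_config(self, rng):
        m = nn.build_model(tiny_cfg(dropout=0.4))
        x = rng.normal(size=(1, 6, 3))
        a, _ = nn.predict(m, x)
        b, _ = nn.predict(m, x)
        np.testing.assert_array_equal(a, b)

    def test_too_short_sequence(self):
        m = nn.build_model(tiny_cfg())
        with pytest.raises(ValueError):
            nn.predict(m, np.zeros((3, 3)), warmup_steps=5)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, rng, tmp_path):
        m = nn.build_model(tiny_cfg())
        m.history = [{"epoch": 0, "train_loss": 0.5, "val_loss": 0.4}]
        path = tmp_path / "model.npz"
        nn.save_checkpoint(m, path, extra={"standardizer": {"x": [0.0, 1.0]}})
        m2, extra = nn.load_checkpoint(path)
        x = rng.normal(size=(2, 7, 3))
        np.testing.assert_array_equal(m.forward(x), m2.forward(x))
        assert extra["standardizer"]["x"] == [0.0, 1.0]
        assert (tmp_path / "model.log.csv").read_text().startswith("epoch,")
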