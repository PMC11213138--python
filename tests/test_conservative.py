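import numpy as np
import pytest
from dataclasses import replace

from promodesign import nn
from promodesign.conservative import (DEFAULT_ALPHAS, InnerAscentConfig,
                                      ascend, conservative_loss,
                                      finetune_conservative, mu_samples,
                                      train_alpha_sweep)
from promodesign.model import (ExpressionModel, TrainConfig, de_contrast,
                               finetune_plain, predict_de)
from promodesign.seq_core import encode_batch

from conftest import random_seqs


@pytest.fixture(scope="module")
def onehot80():
    return encode_batch(random_seqs(16, 80, seed=60))


FAST_INNER = InnerAscentConfig(steps=10)


class TestInnerAscent:
    def test_t_zero_returns_input_exactly(self, toy_trained_model, onehot80):
        out = mu_samples(toy_trained_model, onehot80, "a",
                         InnerAscentConfig(steps=0))
        assert np.array_equal(out, onehot80)

    def test_zero_gradient_fixed_point(self, toy_arch, onehot80):
        """With a constant-output model the ascent never moves: the result
        equals the relaxed starting point softmax(gamma * x)."""
        m = ExpressionModel(toy_arch, seed=0)
        m.head_layers[-1].W.data[:] = 0.0
        m.trained = True
        out = ascend(m, onehot80, "a", FAST_INNER)
        z = 5.0 * np.asarray(onehot80, dtype=np.float32).astype(float)
        z -= z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        start = e / e.sum(axis=-1, keepdims=True)
        assert np.abs(out - start).max() < 1e-9

    def test_ascent_improves_predicted_de(self, toy_trained_model):
        """Mean predicted DE of the relaxed output is at least the input's,
        across several random starting batches."""
        for seed in range(5):
            x = encode_batch(random_seqs(12, 80, seed=61 + seed))
            out = mu_samples(toy_trained_model, x, "a", FAST_INNER)
            before = predict_de(toy_trained_model, x, "a").mean()
            after = predict_de(toy_trained_model, out, "a").mean()
            assert after >= before - 1e-6

    def test_output_rows_are_simplex_points(self, toy_trained_model, onehot80):
        out = mu_samples(toy_trained_model, onehot80, "a", FAST_INNER)
        assert np.allclose(out.sum(axis=-1), 1.0, atol=1e-6)
        assert (out >= 0).all()

    def test_reproducible_bit_for_bit(self, toy_trained_model, onehot80):
        a = mu_samples(toy_trained_model, onehot80, "b", FAST_INNER)
        b = mu_samples(toy_trained_model, onehot80, "b", FAST_INNER)
        assert np.array_equal(a, b)

    def test_model_parameters_untouched(self, toy_trained_model, onehot80):
        before = toy_trained_model.state()
        mu_samples(toy_trained_model, onehot80, "a", FAST_INNER)
        for b, a in zip(before, toy_trained_model.state()):
            assert np.array_equal(b, a)


class _LinearStub:
    """One-position two-cell linear model: pe = x[:, 0, :] @ W."""

    def __init__(self, W):
        self.W = nn.Tensor(W, requires_grad=True)
        self.cell_types = ["a", "b"]
        self.trained = True
        self.config = type("C", (), {"length": 1})

    def parameters(self):
        return [self.W]

    def forward(self, x, training=False, rng=None):
        t = x if isinstance(x, nn.Tensor) else nn.Tensor(x)
        return nn.matmul(t.reshape(t.shape[0], 4), self.W)


class TestConservativeLoss:
    def test_alpha_zero_is_plain_mse(self, toy_trained_model, onehot80):
        y = np.random.default_rng(0).normal(size=(16, 2))
        total, rep = conservative_loss(toy_trained_model, onehot80, y, 0.0,
                                       FAST_INNER)
        per_cell_mse = ((toy_trained_model.forward(onehot80).data - y) ** 2
                        ).mean(axis=0)
        assert total.item() == pytest.approx(per_cell_mse.sum(), rel=1e-5)
        assert all(v == 0.0 for v in rep.regularizer.values())

    def test_negative_alpha_rejected(self, toy_trained_model, onehot80):
        with pytest.raises(ValueError):
            conservative_loss(toy_trained_model, onehot80,
                              np.zeros((16, 2)), -0.1, FAST_INNER)

    def test_report_total_identity(self, toy_trained_model, onehot80):
        y = np.random.default_rng(1).normal(size=(16, 2))
        alpha = 0.05
        total, rep = conservative_loss(toy_trained_model, onehot80, y, alpha,
                                       FAST_INNER)
        recon = (sum(rep.supervised.values())
                 + alpha * sum(rep.regularizer.values()))
        assert rep.total == pytest.approx(recon, rel=1e-4)
        assert rep.total == pytest.approx(total.item(), rel=1e-6)

    def test_single_step_adam_closed_form(self):
        """T=1 with a frozen linear model on a 1-position sequence: the
        regularizer matches a pencil-and-paper Adam step
        (m_hat = g, v_hat = g^2, step = lr * g/(|g|+eps) ~ lr * sign(g))."""
        W = np.array([[1.0, 0.0], [0.0, 1.0],
                      [0.5, 0.5], [0.2, 0.8]])
        model = _LinearStub(W)
        x = np.zeros((1, 1, 4))
        x[0, 0, 0] = 1.0                       # the sequence "A"
        y = np.zeros((1, 2))
        lr = 0.5
        cfg = InnerAscentConfig(lr=lr, steps=1)
        alpha = 1.0
        total, rep = conservative_loss(model, x, y, alpha, cfg)

        # ---- independent closed form ---------------------------------- #
        gamma = 5.0
        z0 = gamma * x[0, 0]
        p0 = np.exp(z0 - z0.max()); p0 /= p0.sum()
        expected = {}
        for c, sign in (("a", 1.0), ("b", -1.0)):
            w_c = W @ (sign * np.array([1.0, -1.0]))   # DE weight per base
            g = -((w_c - p0 @ w_c) * p0)               # grad of -DE wrt logits
            z1 = z0 - lr * np.sign(g)                  # one Adam step
            p1 = np.exp(z1 - z1.max()); p1 /= p1.sum()
            de_mu = float(p1 @ w_c)
            de_data = float(x[0, 0] @ w_c)
            expected[c] = de_mu - de_data
        for c in model.cell_types:
            assert rep.regularizer[c] == pytest.approx(expected[c], abs=1e-4)

    def test_regularizer_nonnegative_when_ascent_starts_on_batch(
            self, toy_trained_model, onehot80):
        y = np.zeros((16, 2))
        _, rep = conservative_loss(toy_trained_model, onehot80, y, 0.1,
                                   InnerAscentConfig(steps=10))
        # ascent improves DE over the relaxed start; the relaxed start's DE
        # is close to the hard batch's, so the gap stays above a small slack
        for v in rep.regularizer.values():
            assert v > -0.1


class TestFinetuneConservative:
    def test_alpha_zero_reproduces_plain(self, toy_arch, toy_panel):
        cfg = TrainConfig(max_epochs=3, patience=3, seed=4, split_seed=0)
        m0 = ExpressionModel(toy_arch, seed=6)
        a = finetune_conservative(m0, toy_panel, 0.0, cfg, FAST_INNER)
        b = finetune_plain(m0, toy_panel, cfg)
        for pa, pb in zip(a.state(), b.state()):
            assert np.array_equal(pa, pb)

    def test_large_alpha_suppresses_adversarial_de(self, toy_trained_model,
                                                   toy_panel):
        """With alpha = 1.0, training drives the predicted DE of the
        optimizer-found mu sequences down toward the data batch's mean:
        the regularizer shrinks to a small fraction of its initial value.
        (It stays non-negative because mu starts from the batch and the
        ascent cannot do worse than its starting point.)"""
        cfg = TrainConfig(max_epochs=15, patience=15, seed=0, split_seed=0,
                          lr=1e-3)
        inner = InnerAscentConfig(steps=10, mu_batch=16)
        log = []
        finetune_conservative(toy_trained_model, toy_panel, 1.0, cfg, inner,
                              log=log)
        regs = [sum(r.regularizer.values()) for r in log]
        initial = np.mean(regs[:3])
        final = np.mean(regs[-3:])
        assert final < 0.3 * initial

    def test_small_alpha_keeps_validation_fit(self, toy_arch, toy_panel):
        """alpha = 0.001 conservative fine-tuning stays within 20% of the
        plain model's validation loss."""
        from promodesign.model import split_panel, evaluate
        cfg = TrainConfig(max_epochs=12, patience=12, seed=0, split_seed=0)
        inner = InnerAscentConfig(steps=10, mu_batch=16)
        plain = finetune_plain(ExpressionModel(toy_arch, seed=8), toy_panel, cfg)
        cons = finetune_conservative(ExpressionModel(toy_arch, seed=8),
                                     toy_panel, 0.001, cfg, inner)
        _, va, _ = split_panel(len(toy_panel), cfg)
        mse_p = evaluate(plain, toy_panel, va)["mse"]
        mse_c = evaluate(cons, toy_panel, va)["mse"]
        assert mse_c <= 1.2 * mse_p


class TestAlphaSweep:
    def test_single_zero_alpha(self, toy_trained_model, toy_panel):
        cfg = TrainConfig(max_epochs=2, patience=2)
        out = train_alpha_sweep(toy_trained_model, toy_panel, alphas=[0.0],
                                train_cfg=cfg, inner_cfg=FAST_INNER)
        assert len(out) == 1 and out[0].alpha == 0.0

    def test_default_sweep_has_six_alphas(self):
        assert DEFAULT_ALPHAS == (0.0, 0.0003, 0.001, 0.003, 0.01, 0.03)

    def test_models_share_architecture_hash(self, toy_trained_model, toy_panel):
        cfg = TrainConfig(max_epochs=1, patience=1)
        inner = InnerAscentConfig(steps=2, mu_batch=8)
        out = train_alpha_sweep(toy_trained_model, toy_panel,
                                alphas=[0.0, 0.01], train_cfg=cfg,
                                inner_cfg=inner)
        assert len({dm.arch_hash for dm in out}) == 1
        assert [dm.alpha for dm in out] == [0.0, 0.01]

    def test_negative_alpha_rejected(self, toy_trained_model, toy_panel):
        with pytest.raises(ValueError):
            train_alpha_sweep(toy_trained_model, toy_panel, alphas=[-1.0])

    def test_empty_alphas_rejected(self, toy_trained_model, toy_panel):
        with pytest.raises(ValueError):
            train_alpha_sweep(toy_trained_model, toy_panel, alphas=[])
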