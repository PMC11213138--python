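import numpy as np
import pytest

from promodesign.model import (ExpressionModel, ModelConfig, TrainConfig,
                               de_contrast, evaluate, finetune_plain,
                               predict_de, predict_pe, pretrain, split_panel,
                               transfer)
from promodesign.oracle import generate_panel
from promodesign.seq_core import encode_batch

from conftest import random_seqs


@pytest.fixture(scope="module")
def onehot_batch():
    return encode_batch(random_seqs(12, 80, seed=30))


class TestForward:
    def test_zero_head_predicts_zero(self, toy_arch, onehot_batch):
        m = ExpressionModel(toy_arch, seed=0)
        m.head_layers[-1].W.data[:] = 0.0
        m.head_layers[-1].b.data[:] = 0.0
        assert np.allclose(predict_pe(m, onehot_batch), 0.0)

    def test_eval_deterministic(self, toy_trained_model, onehot_batch):
        p1 = predict_pe(toy_trained_model, onehot_batch)
        p2 = predict_pe(toy_trained_model, onehot_batch)
        assert np.array_equal(p1, p2)

    def test_continuity_near_one_hot(self, toy_trained_model, onehot_batch):
        """Predictions on a near-vertex simplex point stay close to the
        hard one-hot predictions."""
        soft = onehot_batch * 0.997 + 0.001
        soft = soft / soft.sum(axis=-1, keepdims=True)
        p_hard = predict_pe(toy_trained_model, onehot_batch)
        p_soft = predict_pe(toy_trained_model, soft)
        assert np.abs(p_hard - p_soft).max() < 1e-1

    def test_wrong_length_rejected(self, toy_trained_model):
        bad = encode_batch(random_seqs(2, 60, seed=31))
        with pytest.raises(ValueError, match="shape"):
            predict_pe(toy_trained_model, bad)

    def test_rows_must_be_simplex(self, toy_trained_model, onehot_batch):
        with pytest.raises(ValueError, match="sum to 1"):
            predict_pe(toy_trained_model, onehot_batch * 2.0)


class TestPredictDe:
    def test_identical_heads_zero_de(self, toy_arch, onehot_batch):
        m = ExpressionModel(toy_arch, seed=1)
        W = m.head_layers[-1].W
        W.data[:, 1] = W.data[:, 0]
        m.head_layers[-1].b.data[:] = 0.3
        de = predict_de(m, onehot_batch, "a")
        assert np.allclose(de, 0.0, atol=1e-5)

    def test_contrast_arithmetic(self):
        a = de_contrast(["t", "o1", "o2"], "t")
        assert np.array([5.0, 2.0, 1.0]) @ a == pytest.approx(3.5)

    def test_two_cell_antisymmetry(self, toy_trained_model, onehot_batch):
        d_a = predict_de(toy_trained_model, onehot_batch, "a")
        d_b = predict_de(toy_trained_model, onehot_batch, "b")
        assert np.allclose(d_a + d_b, 0.0, atol=1e-5)

    def test_de_linear_in_pe(self, toy_trained_model, onehot_batch):
        pe = predict_pe(toy_trained_model, onehot_batch)
        a = de_contrast(toy_trained_model.cell_types, "b")
        assert np.allclose(predict_de(toy_trained_model, onehot_batch, "b"),
                           pe @ a, atol=1e-6)

    def test_unknown_target_rejected(self, toy_trained_model, onehot_batch):
        with pytest.raises(KeyError):
            predict_de(toy_trained_model, onehot_batch, "nope")


class TestTraining:
    def test_zero_epochs_leaves_parameters(self, toy_arch, toy_panel):
        m = ExpressionModel(toy_arch, seed=2)
        before = [p.copy() for p in m.state()]
        out = finetune_plain(m, toy_panel,
                             TrainConfig(max_epochs=0))
        for b, a in zip(before, out.state()):
            assert np.array_equal(b, a)

    def test_loss_decreases_early(self, toy_arch, toy_panel):
        from promodesign import nn
        from promodesign.model import supervised_loss
        m = ExpressionModel(toy_arch, seed=3)
        X = encode_batch(toy_panel.sequences[:64])
        Y = toy_panel.expression[:64]
        opt = nn.Adam(m.parameters(), lr=3e-3)
        first = supervised_loss(m, X, Y).item()
        for _ in range(10):
            opt.zero_grad()
            loss = supervised_loss(m, X, Y)
            loss.backward()
            opt.step()
        assert loss.item() < first

    def test_trainability_gate(self, toy_trained_model, toy_panel):
        """Fine-tuned model reaches r >= 0.6 against the noise-free truth
        on the held-out split of its training panel."""
        cfg = TrainConfig(max_epochs=60, patience=60, batch_size=64, lr=3e-3,
                          split_seed=0, seed=0)
        _, _, te = split_panel(len(toy_panel), cfg)
        ev = evaluate(toy_trained_model, toy_panel, te, use_true=True)
        assert ev["pearson_a"] >= 0.6

    def test_split_deterministic_and_disjoint(self):
        cfg = TrainConfig(split_seed=5)
        tr, va, te = split_panel(100, cfg)
        tr2, va2, te2 = split_panel(100, cfg)
        assert np.array_equal(tr, tr2)
        assert len(set(tr) | set(va) | set(te)) == 100

    def test_pretrain_empty_corpora_rejected(self, toy_arch):
        with pytest.raises(ValueError):
            pretrain(ExpressionModel(toy_arch, seed=0), [], TrainConfig())

    def test_transfer_copies_backbone_resets_head(self, toy_trained_model):
        t = transfer(toy_trained_model, ["x", "y", "z"], head="linear", seed=9)
        assert t.cell_types == ["x", "y", "z"]
        for b, a in zip(toy_trained_model.backbone_state(),
                        t.backbone_state()):
            assert np.array_equal(b, a)
        assert not t.trained

    def test_pretrain_then_finetune_beats_scratch(self, two_cell_grammar,
                                                  toy_arch, toy_panel):
        """Transfer from a related-context corpus improves held-out fit at
        small n, paired over 3 seeds."""
        from dataclasses import replace
        from promodesign.pipeline import pretraining_grammar
        pg = pretraining_grammar(two_cell_grammar, 99)
        corpus = generate_panel(pg, 800, 80, planting_rate=0.3, seed=40,
                                id_prefix="pre")
        pm = pretrain(ExpressionModel(replace(toy_arch,
                                              cell_types=tuple(pg.cell_types)),
                                      seed=0),
                      [corpus],
                      TrainConfig(max_epochs=40, patience=40, lr=3e-3))
        small = generate_panel(two_cell_grammar, 150, 80, planting_rate=0.3,
                               seed=41)
        cfg = TrainConfig(max_epochs=40, patience=40, lr=1.5e-3, split_seed=0)
        _, _, te = split_panel(len(small), cfg)
        diffs = []
        for seed in range(3):
            ft = finetune_plain(transfer(pm, small.cell_types, seed=seed),
                                small, replace(cfg, seed=seed))
            sc = finetune_plain(
                ExpressionModel(replace(toy_arch,
                                        cell_types=tuple(small.cell_types)),
                                seed=seed),
                small, replace(cfg, seed=seed))
            diffs.append(evaluate(sc, small, te)["mse"]
                         - evaluate(ft, small, te)["mse"])
        assert np.mean(diffs) > 0.0


def test_trainability_gate_on_default_panel(pretrained_backbone,
                                            default_oracle):
    """On the default oracle panel (3,000 sequences of 250 bp), a
    fine-tuned model reaches Pearson r >= 0.6 against the noise-free truth
    per cell type on the held-out split — the trainability gate for all
    downstream design tests."""
    g, _ = default_oracle
    panel = generate_panel(g, 3000, 250, seed=2)
    cfg = TrainConfig(max_epochs=30, patience=10, lr=1e-3, split_seed=0,
                      seed=0)
    _, _, te = split_panel(len(panel), cfg)
    model = finetune_plain(
        transfer(pretrained_backbone, g.cell_types, length=250, seed=4),
        panel, cfg)
    ev = evaluate(model, panel, te, use_true=True)
    for c in g.cell_types:
        assert ev[f"pearson_{c}"] >= 0.6
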