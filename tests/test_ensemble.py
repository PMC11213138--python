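import numpy as np
import pytest
from dataclasses import replace

from promodesign import nn
from promodesign.designer import Candidate, CandidatePool
from promodesign.ensemble import (Ensemble, PessimisticScore, build_ensemble,
                                  filter_candidates, score_candidates)
from promodesign.model import TrainConfig, evaluate, predict_pe, split_panel
from promodesign.seq_core import DnaSequence, encode_batch

from conftest import random_seqs


class _AContentModel:
    """Stub predictor: pe = (f - 0.5 + shift, -(f - 0.5)) with f the
    fraction of A bases — fully controllable scores for filter tests."""

    def __init__(self, shift=0.0):
        self.cell_types = ["t", "o"]
        self.trained = True
        self.shift = shift
        self.config = type("C", (), {"length": None})

    def parameters(self):
        return []

    def forward(self, x, training=False, rng=None):
        t = x if isinstance(x, nn.Tensor) else nn.Tensor(x)
        f = t.data[..., 0].mean(axis=1)
        return nn.Tensor(np.stack([f - 0.5 + self.shift, -(f - 0.5)], axis=1))


def _pool_from(seqs, target="t"):
    cands = [Candidate(sequence=s, starting_id=f"s{i}", alpha=0.0,
                       model_id="m", predicted_de=0.0, target_cell=target)
             for i, s in enumerate(seqs)]
    return CandidatePool(cands, target)


def _seq(frac_a, L=20, sid="x"):
    n_a = int(round(frac_a * L))
    return DnaSequence(sid, "A" * n_a + "C" * (L - n_a))


class TestScores:
    def test_population_sd_arithmetic(self):
        s = PessimisticScore("c", mean_de=2.0, sd_de=float(np.sqrt(2 / 3)),
                             lcb_de=2.0 - float(np.sqrt(2 / 3)),
                             mean_pe=(0.0,))
        assert s.lcb_de == pytest.approx(2.0 - 0.816497, abs=1e-5)

    def test_lcb_identity_enforced(self):
        with pytest.raises(ValueError):
            PessimisticScore("c", mean_de=1.0, sd_de=0.5, lcb_de=0.9,
                             mean_pe=(0.0,))

    def test_member_spread_gives_population_sd(self):
        """Member DE predictions {1, 2, 3} -> mean 2, population SD
        sqrt(2/3), LCB = 2 - sqrt(2/3)."""
        members = [_AContentModel(shift=d) for d in (0.0, 1.0, 2.0)]
        # DE under the stub = 2(f-0.5) + shift; f=0.75 -> DE in {0.5, 1.5, 2.5}
        e = Ensemble(members=members, split_seed=1, member_ids=list("abc"))
        pool = _pool_from([_seq(0.75)])
        (score,) = score_candidates(e, pool, "t")
        assert score.mean_de == pytest.approx(1.5, abs=1e-6)
        assert score.sd_de == pytest.approx(np.sqrt(2 / 3), abs=1e-6)
        assert score.lcb_de == pytest.approx(score.mean_de - score.sd_de)

    def test_identical_members_zero_sd(self):
        members = [_AContentModel(), _AContentModel()]
        e = Ensemble(members=members, split_seed=1, member_ids=["a", "b"])
        (score,) = score_candidates(e, _pool_from([_seq(0.6)]), "t")
        assert score.sd_de == 0.0
        assert score.lcb_de == score.mean_de

    def test_single_member_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            Ensemble(members=[_AContentModel()], split_seed=1,
                     member_ids=["a"])


class TestFilter:
    def test_filter_rule_enumeration(self, toy_panel):
        """Keep exactly the candidates with positive mean DE AND predicted
        target expression at or above the panel median."""
        from promodesign.oracle import SequencePanel
        e = Ensemble(members=[_AContentModel(), _AContentModel()],
                     split_seed=1, member_ids=["a", "b"])
        # panel of random sequences: f ~ 0.25, target pe ~ -0.25 (median)
        panel = SequencePanel(random_seqs(50, 20, seed=80),
                              np.zeros((50, 2)), ["t", "o"])
        # candidates: (DE sign, expression vs median):
        #   f=0.9 -> +,above ; f=0.7 -> +,above ; f=0.1 -> -,below ;
        #   f=0.55 -> +,above ; f=0.3 -> -,above
        pool = _pool_from([_seq(f, sid=f"c{i}")
                           for i, f in enumerate((0.9, 0.7, 0.1, 0.55, 0.3))])
        scores = score_candidates(e, pool, "t")
        kept, kept_scores = filter_candidates(scores, pool, e, panel,
                                              expression_quantile=0.5)
        assert [c.starting_id for c in kept.candidates] == ["s0", "s1", "s3"]
        assert len(kept_scores) == 3

    def test_all_nonpositive_de_empty(self, caplog):
        from promodesign.oracle import SequencePanel
        e = Ensemble(members=[_AContentModel(), _AContentModel()],
                     split_seed=1, member_ids=["a", "b"])
        panel = SequencePanel(random_seqs(30, 20, seed=81),
                              np.zeros((30, 2)), ["t", "o"])
        pool = _pool_from([_seq(0.1, sid="lo1"), _seq(0.2, sid="lo2")])
        scores = score_candidates(e, pool, "t")
        with caplog.at_level("WARNING"):
            kept, _ = filter_candidates(scores, pool, e, panel)
        assert len(kept) == 0
        assert any("removed every" in r.message for r in caplog.records)

    def test_quantile_zero_reduces_to_de_filter(self, toy_panel):
        from promodesign.oracle import SequencePanel
        e = Ensemble(members=[_AContentModel(), _AContentModel()],
                     split_seed=1, member_ids=["a", "b"])
        panel = SequencePanel(random_seqs(30, 20, seed=82),
                              np.zeros((30, 2)), ["t", "o"])
        pool = _pool_from([_seq(f, sid=f"q{i}")
                           for i, f in enumerate((0.9, 0.3, 0.6))])
        scores = score_candidates(e, pool, "t")
        kept, _ = filter_candidates(scores, pool, e, panel,
                                    expression_quantile=0.0)
        assert [c.starting_id for c in kept.candidates] == ["s0", "s2"]

    def test_misaligned_scores_rejected(self):
        e = Ensemble(members=[_AContentModel(), _AContentModel()],
                     split_seed=1, member_ids=["a", "b"])
        pool = _pool_from([_seq(0.5)])
        with pytest.raises(ValueError, match="aligned"):
            filter_candidates([], pool, e, None)


@pytest.fixture(scope="module")
def trained_ensemble(toy_trained_model, toy_panel):
    cfg = TrainConfig(max_epochs=25, patience=25, lr=1.5e-3)
    return build_ensemble(toy_trained_model, toy_panel, size=3,
                          base_cfg=cfg, split_seed=11, design_split_seed=0,
                          seed=2)


class TestBuiltEnsemble:
    def test_same_split_seed_rejected(self, toy_trained_model, toy_panel):
        with pytest.raises(ValueError, match="differ"):
            build_ensemble(toy_trained_model, toy_panel, size=2,
                           split_seed=0, design_split_seed=0)

    def test_members_heterogeneous(self, trained_ensemble):
        heads = {m.config.head for m in trained_ensemble.members}
        assert len(heads) >= 2

    def test_ensemble_mean_not_worse_than_median_member(self, trained_ensemble,
                                                        toy_panel):
        """Held-out MSE of the ensemble-mean prediction <= the median
        member's MSE."""
        cfg = TrainConfig(split_seed=11)
        _, _, te = split_panel(len(toy_panel), cfg)
        X = encode_batch([toy_panel.sequences[i] for i in te])
        Y = toy_panel.expression[te]
        preds = np.stack([predict_pe(m, X) for m in trained_ensemble.members])
        member_mses = ((preds - Y) ** 2).mean(axis=(1, 2))
        ens_mse = ((preds.mean(axis=0) - Y) ** 2).mean()
        assert ens_mse <= np.median(member_mses) + 1e-9

    def test_uncertainty_larger_on_designed_sequences(self, trained_ensemble,
                                                      toy_trained_model,
                                                      toy_panel):
        """Ensemble SD inflates on optimizer-designed (off-distribution)
        sequences relative to training-distribution sequences — the
        uncertainty signal the pessimistic LCB exploits."""
        from promodesign.conservative import InnerAscentConfig, ascend
        from promodesign.seq_core import discretize
        originals = toy_panel.sequences[:60]
        probs = ascend(toy_trained_model, encode_batch(originals), "a",
                       InnerAscentConfig(steps=20))
        designed = [discretize(probs[i], f"d{i}") for i in range(len(originals))]
        sd_orig = np.mean([s.sd_de for s in score_candidates(
            trained_ensemble, _pool_from(originals, "a"), "a")])
        sd_designed = np.mean([s.sd_de for s in score_candidates(
            trained_ensemble, _pool_from(designed, "a"), "a")])
        assert sd_designed > sd_orig
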