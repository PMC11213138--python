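import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from promodesign.model import (ExpressionModel, ModelConfig, TrainConfig,
                               finetune_plain)
from promodesign.oracle import (Motif, MotifGrammar, default_grammar,
                                generate_panel, _sharp_pwm)
from promodesign.seq_core import DnaSequence


def random_seqs(n, L, seed=0, prefix="r"):
    rng = np.random.default_rng(seed)
    return [DnaSequence(f"{prefix}{i}", "".join("ACGT"[b] for b in rng.integers(0, 4, L)))
            for i in range(n)]


@pytest.fixture(scope="session")
def grammar():
    """The default three-cell-type grammar (cellC is the hard target)."""
    return default_grammar(seed=1)


@pytest.fixture(scope="session")
def tiny_panel(grammar):
    """A small labelled panel for fast unit tests."""
    return generate_panel(grammar, 120, 80, seed=2)


@pytest.fixture(scope="session")
def two_cell_grammar():
    rng = np.random.default_rng(7)
    ma = Motif("priv_a", _sharp_pwm(rng.integers(0, 4, 8)),
               {"a": 1.5, "b": 0.0})
    mb = Motif("priv_b", _sharp_pwm(rng.integers(0, 4, 8)),
               {"a": 0.0, "b": 1.0})
    return MotifGrammar(["a", "b"], [ma, mb], {"a": 2.0, "b": 2.0},
                        noise_sd=0.1, seed=7)


@pytest.fixture(scope="session")
def toy_arch():
    return ModelConfig(length=80, cell_types=("a", "b"),
                       conv_channels=(32,), conv_width=12, pool=2,
                       attn_blocks=1, attn_heads=2)


@pytest.fixture(scope="session")
def toy_panel(two_cell_grammar):
    return generate_panel(two_cell_grammar, 600, 80, planting_rate=0.3, seed=3)


@pytest.fixture(scope="session")
def toy_trained_model(toy_panel, toy_arch):
    """A small model fine-tuned on a two-cell-type oracle panel; shared
    across tests that need a competent trained predictor."""
    cfg = TrainConfig(max_epochs=80, patience=80, batch_size=64, lr=3e-3,
                      split_seed=0, seed=0)
    return finetune_plain(ExpressionModel(toy_arch, seed=5), toy_panel, cfg)


@pytest.fixture(scope="session")
def smoke_run(tmp_path_factory):
    """One full end-to-end workflow run at the desk-scale smoke settings,
    shared by the workflow-quality and acceptance tests."""
    from promodesign.pipeline import run_pipeline, smoke_config
    out = tmp_path_factory.mktemp("smoke_run")
    manifest = run_pipeline(smoke_config(seed=1), out)
    return out, manifest


@pytest.fixture(scope="session")
def default_oracle():
    """Default grammar + smoke-scale fine-tuning panel (the study
    conditions of the end-to-end tests)."""
    g = default_grammar(seed=1)
    panel = generate_panel(g, 400, 120, seed=2)
    return g, panel


@pytest.fixture(scope="session")
def pretrained_backbone(default_oracle):
    """Backbone pretrained on a related-context corpus; shared by the
    trainability gate and the conservatism study."""
    from promodesign.model import pretrain
    from promodesign.pipeline import pretraining_grammar
    g, _ = default_oracle
    pg = pretraining_grammar(g, 11)
    corpus = generate_panel(pg, 3000, 120, seed=12, id_prefix="pre")
    cfg = TrainConfig(max_epochs=120, patience=25, lr=3e-3, seed=0)
    model = ExpressionModel(
        ModelConfig(length=120, cell_types=tuple(pg.cell_types)), seed=3)
    return pretrain(model, [corpus], cfg)
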