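"""Why conservative training matters: the adversarial-design gap.

Trains two design models on the same data — one plain (alpha = 0), one
with the conservative regularizer (alpha = 0.01) — designs a sequence
pool with each by gradient ascent in the probability simplex, and
compares how much each model overestimates its own designs' DE relative
to the oracle's ground truth. Takes a couple of minutes on one CPU.
"""

import numpy as np

from promodesign.conservative import InnerAscentConfig, train_alpha_sweep
from promodesign.designer import design_pool
from promodesign.model import (ExpressionModel, ModelConfig, TrainConfig,
                               pretrain, transfer)
from promodesign.oracle import default_grammar, generate_panel, true_de_batch
from promodesign.pipeline import pretraining_grammar

grammar = default_grammar(seed=1)
panel = generate_panel(grammar, n=400, L=120, seed=2)

# pretrain a backbone on a larger related-context corpus, then fine-tune
pre = pretraining_grammar(grammar, seed=11)
corpus = generate_panel(pre, n=3000, L=120, seed=12, id_prefix="pre")
backbone = pretrain(
    ExpressionModel(ModelConfig(120, tuple(pre.cell_types)), seed=3),
    [corpus], TrainConfig(max_epochs=120, patience=25, lr=3e-3))

inner = InnerAscentConfig(steps=20, mu_batch=32)
sweep = train_alpha_sweep(
    transfer(backbone, grammar.cell_types, seed=4), panel,
    alphas=(0.0, 0.01),
    train_cfg=TrainConfig(max_epochs=35, patience=10, lr=1e-3, seed=0),
    inner_cfg=inner)

target = grammar.cell_types[0]
for dm in sweep:
    pool = design_pool([dm], panel, target, inner, master_seed=0)
    predicted = np.array([c.predicted_de for c in pool.candidates])
    true = true_de_batch(pool.sequences(), grammar, target)
    print(f"alpha={dm.alpha:<5}: designed {len(pool)} candidates | "
          f"predicted DE {predicted.mean():.2f} | oracle true DE "
          f"{true.mean():.2f} | overestimate {predicted.mean() - true.mean():.2f}")
print("The plain model (alpha=0) overestimates its designs more than the "
      "conservative one — the adversarial gap the regularizer shrinks.")
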