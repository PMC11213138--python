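"""Multi-task promoter-expression models.

A single network predicts promoter-driven expression (PE) in every cell
type of the panel simultaneously: a convolutional feature extractor
followed by self-attention blocks and a per-panel output head. Predicted
differential expression (DE) for a target cell type is the mean contrast
of the target head against all other heads, so it is differentiable with
respect to the input and can be ascended directly.

The forward pass accepts any (batch, L, 4) real matrix whose rows sum
to 1 — hard one-hot encodings and relaxed simplex points go down the same
code path.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import nn
from .oracle import SequencePanel
from .seq_core import encode_batch

__all__ = ["ModelConfig", "TrainConfig", "ExpressionModel", "de_contrast",
           "predict_pe", "predict_de", "split_panel", "pretrain",
           "finetune_plain", "transfer", "evaluate"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of an expression model (cell-type panel included)."""

    length: int
    cell_types: tuple[str, ...]
    conv_channels: tuple[int, ...] = (32,)
    conv_width: int = 12
    pool: int = 6
    attn_blocks: int = 1
    attn_heads: int = 4
    head: str = "linear"             # "linear" | "hidden" | "attnpool"
    head_hidden: int = 32
    pool_mode: str = "max"           # pre-head pooling: "max" | "mean"
    first_activation: str = "exp"    # first conv activation: "exp" | "relu"
    dropout: float = 0.0

    def arch_hash(self) -> str:
        """Hash of the architecture fields shared across an α sweep (head
        and panel included; dropout excluded as it only affects training)."""
        payload = {k: v for k, v in self.__dict__.items() if k != "dropout"}
        return hashlib.md5(json.dumps(payload, sort_keys=True,
                                      default=str).encode()).hexdigest()[:12]


@dataclass
class TrainConfig:
    """Optimization settings for (pre)training and fine-tuning."""

    lr: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 60
    patience: int = 10
    val_frac: float = 0.15
    test_frac: float = 0.10
    split_seed: int = 0
    seed: int = 0                    # shuffling / dropout randomness
    alpha: float = 0.0               # conservatism coefficient

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("conservatism coefficient alpha must be >= 0")
        if not 0 < 1.0 - self.val_frac - self.test_frac <= 1.0:
            raise ValueError("split fractions must leave a positive train set")


class ExpressionModel(nn.Module):
    """Conv + self-attention backbone with one output per cell type."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.cell_types = list(config.cell_types)
        rng = np.random.default_rng(seed)
        self.conv = []
        c_in = 4
        for i, c_out in enumerate(config.conv_channels):
            act = config.first_activation if i == 0 else "relu"
            self.conv.append(nn.Conv1dBlock(c_in, c_out, config.conv_width,
                                            config.pool, rng, activation=act))
            c_in = c_out
        self.attn = [nn.SelfAttentionBlock(c_in, config.attn_heads, rng)
                     for _ in range(config.attn_blocks)]
        self.embed_dim = c_in
        if config.head == "linear":
            self.head_layers = [nn.Dense(c_in, len(self.cell_types), rng)]
        elif config.head == "hidden":
            self.head_layers = [nn.Dense(c_in, config.head_hidden, rng),
                                nn.Dense(config.head_hidden,
                                         len(self.cell_types), rng)]
        elif config.head == "attnpool":
            self.head_layers = [nn.AttentionPool(c_in, rng),
                                nn.Dense(c_in, len(self.cell_types), rng)]
        else:
            raise ValueError(f"unknown head type {config.head!r}")
        self.trained = False

    # -- parameter groups ------------------------------------------------
    def backbone_modules(self) -> list[nn.Module]:
        return [*self.conv, *self.attn]

    def backbone_state(self) -> list[np.ndarray]:
        return [p.data.copy() for m in self.backbone_modules()
                for p in m.parameters()]

    def load_backbone_state(self, state: list[np.ndarray]) -> None:
        params = [p for m in self.backbone_modules() for p in m.parameters()]
        if len(params) != len(state):
            raise ValueError("backbone state mismatch")
        for p, s in zip(params, state):
            p.data = s.copy()

    # -- forward ---------------------------------------------------------
    def forward(self, x, training: bool = False,
                rng: np.random.Generator | None = None) -> nn.Tensor:
        h = x if isinstance(x, nn.Tensor) else nn.Tensor(x)
        if h.ndim != 3 or h.shape[1] != self.config.length or h.shape[2] != 4:
            raise ValueError(
                f"expected input of shape (n, {self.config.length}, 4), "
                f"got {tuple(h.shape)}")
        for block in self.conv:
            h = block(h)
        for block in self.attn:
            h = block(h)
        if self.config.dropout > 0 and training:
            h = nn.dropout(h, self.config.dropout, rng, training)
        if self.config.head == "attnpool":
            pooled = self.head_layers[0](h)
            return self.head_layers[1](pooled)
        if self.config.pool_mode == "max":
            pooled = nn.maxpool1d(h, h.shape[1]).reshape(h.shape[0], h.shape[2])
        else:
            pooled = h.mean(axis=1)
        if self.config.head == "hidden":
            pooled = nn.relu(self.head_layers[0](pooled))
            return self.head_layers[1](pooled)
        return self.head_layers[0](pooled)

    def clone(self) -> "ExpressionModel":
        m = ExpressionModel(self.config, seed=0)
        m.load_state(self.state())
        m.trained = self.trained
        return m


# ----------------------------------------------------------------------- #
def de_contrast(cell_types: Sequence[str], target: str) -> np.ndarray:
    """Contrast vector a with DE = PE @ a: +1 on the target cell type and
    −1/(|C|−1) on every other cell type."""
    cts = list(cell_types)
    if target not in cts:
        raise KeyError(f"unknown target cell type {target!r}")
    if len(cts) < 2:
        raise ValueError("DE requires at least two cell types")
    a = np.full(len(cts), -1.0 / (len(cts) - 1))
    a[cts.index(target)] = 1.0
    return a


def predict_pe(model: ExpressionModel, x: np.ndarray) -> np.ndarray:
    """Predicted expression (n, |C|) for a batch of (L, 4) simplex matrices."""
    x = np.asarray(x, dtype=float)
    if not np.allclose(x.sum(axis=-1), 1.0, atol=1e-4):
        raise ValueError("input rows must sum to 1 (one-hot or simplex point)")
    return model.forward(x).data


def predict_de(model: ExpressionModel, x: np.ndarray, target: str) -> np.ndarray:
    """Predicted DE per sequence: the target-vs-rest mean contrast of
    predicted expression. Linear in the predictions."""
    return predict_pe(model, x) @ de_contrast(model.cell_types, target)


def de_tensor(model: ExpressionModel, x, target: str) -> nn.Tensor:
    """Graph-building version of :func:`predict_de` (vector of n DE values)."""
    a = de_contrast(model.cell_types, target)
    pe = model.forward(x)
    return nn.matmul(pe, nn.Tensor(a[:, None])).reshape(pe.shape[0])


__all__.append("de_tensor")


# ----------------------------------------------------------------------- #
# training
# ----------------------------------------------------------------------- #

def split_panel(n: int, cfg: TrainConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic train/val/test index split."""
    order = np.random.default_rng(cfg.split_seed).permutation(n)
    n_test = int(round(n * cfg.test_frac))
    n_val = int(round(n * cfg.val_frac))
    return order[n_test + n_val:], order[n_test:n_test + n_val], order[:n_test]


def _masked_mse(pred: nn.Tensor, y: np.ndarray) -> nn.Tensor:
    """Sum over cell types of per-type MSE; NaN labels are ignored (used for
    pretraining on stacked corpora with disjoint label columns)."""
    mask = ~np.isnan(y)
    y0 = np.where(mask, y, 0.0)
    counts = np.maximum(mask.sum(axis=0), 1)
    se = (pred - nn.Tensor(y0)) * nn.Tensor(mask.astype(float))
    return ((se ** 2).sum(axis=0) / nn.Tensor(counts.astype(float))).sum()


def supervised_loss(model: ExpressionModel, x: np.ndarray, y: np.ndarray,
                    training: bool = False,
                    rng: np.random.Generator | None = None) -> nn.Tensor:
    return _masked_mse(model.forward(x, training=training, rng=rng), y)


def _val_loss(model: ExpressionModel, X: np.ndarray, y: np.ndarray,
              batch: int = 256) -> float:
    tot, cnt = 0.0, 0
    for i in range(0, len(X), batch):
        xb, yb = X[i:i + batch], y[i:i + batch]
        tot += supervised_loss(model, xb, yb).item() * len(xb)
        cnt += len(xb)
    return tot / max(cnt, 1)


def fit(model: ExpressionModel, X: np.ndarray, Y: np.ndarray,
        cfg: TrainConfig, step_loss=None, log: list | None = None
        ) -> ExpressionModel:
    """Generic training loop with early stopping on the supervised
    validation loss; returns a copy of the model at the best checkpoint.

    ``step_loss(model, xb, yb, rng) -> Tensor`` overrides the per-batch loss
    (the conservative objective plugs in here); validation always uses the
    plain supervised loss so checkpoints are comparable across objectives.
    """
    model = model.clone()
    if cfg.max_epochs <= 0:
        model.trained = True
        return model
    tr, va, _ = split_panel(len(X), cfg)
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    best_val, best_state, wait = np.inf, model.state(), 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(tr)
        train_losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            opt.zero_grad()
            if step_loss is None:
                loss = supervised_loss(model, X[idx], Y[idx],
                                       training=True, rng=rng)
            else:
                loss = step_loss(model, X[idx], Y[idx], rng)
            loss.backward()
            opt.step()
            train_losses.append(loss.item())
        val = _val_loss(model, X[va], Y[va]) if len(va) else _val_loss(model, X[tr], Y[tr])
        if log is not None:
            log.append({"epoch": epoch,
                        "train_loss": float(np.mean(train_losses)),
                        "val_loss": val})
        if val < best_val - 1e-9:
            best_val, best_state, wait = val, model.state(), 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break
    model.load_state(best_state)
    model.trained = True
    return model


def pretrain(model: ExpressionModel, corpora: Sequence[SequencePanel],
             cfg: TrainConfig, log: list | None = None) -> ExpressionModel:
    """Supervised multi-task pretraining on one or more corpora.

    Corpora are stacked with one head per corpus cell type; a sample only
    contributes loss on its own corpus's label columns. The model's panel
    must equal the concatenation of the corpora's cell types.
    """
    corpora = list(corpora)
    if not corpora:
        raise ValueError("pretraining requires at least one corpus")
    all_cts = [c for panel in corpora for c in panel.cell_types]
    if len(set(all_cts)) != len(all_cts):
        raise ValueError("corpus cell-type names must be globally unique")
    if model.cell_types != all_cts:
        raise ValueError("model heads must match the concatenated corpora "
                         f"cell types {all_cts}")
    Xs, Ys, offset = [], [], 0
    for panel in corpora:
        X = encode_batch(panel.sequences)
        Y = np.full((len(panel), len(all_cts)), np.nan)
        Y[:, offset:offset + len(panel.cell_types)] = panel.expression
        offset += len(panel.cell_types)
        Xs.append(X)
        Ys.append(Y)
    return fit(model, np.concatenate(Xs), np.concatenate(Ys), cfg, log=log)


def transfer(pretrained: ExpressionModel, cell_types: Sequence[str],
             head: str = "linear", dropout: float | None = None,
             length: int | None = None, seed: int = 0) -> ExpressionModel:
    """Re-head a pretrained model for a new cell-type panel: the backbone is
    copied, the output head is freshly initialized.

    The backbone (convolutions, content-based attention, global pooling)
    is length-agnostic, so the new model may use a different sequence
    length than the pretraining corpus."""
    cfg = replace(pretrained.config, cell_types=tuple(cell_types), head=head,
                  length=pretrained.config.length if length is None else length,
                  dropout=pretrained.config.dropout if dropout is None else dropout)
    m = ExpressionModel(cfg, seed=seed)
    m.load_backbone_state(pretrained.backbone_state())
    return m


def finetune_plain(model: ExpressionModel, panel: SequencePanel,
                   cfg: TrainConfig, log: list | None = None
                   ) -> ExpressionModel:
    """MSE-only fine-tuning on the panel; best-validation checkpoint."""
    if model.cell_types != list(panel.cell_types):
        raise ValueError("model heads do not match the panel cell types")
    X = encode_batch(panel.sequences)
    return fit(model, X, panel.expression, cfg, log=log)


def evaluate(model: ExpressionModel, panel: SequencePanel,
             idx: np.ndarray | None = None, use_true: bool = False
             ) -> dict[str, float]:
    """Held-out per-cell-type Pearson r and overall MSE."""
    if idx is None:
        idx = np.arange(len(panel))
    X = encode_batch([panel.sequences[i] for i in idx])
    Y = (panel.true_values if use_true and panel.true_values is not None
         else panel.expression)[idx]
    pred = np.concatenate([predict_pe(model, X[i:i + 256])
                           for i in range(0, len(X), 256)])
    out = {"mse": float(np.mean((pred - Y) ** 2))}
    for j, c in enumerate(model.cell_types):
        out[f"pearson_{c}"] = float(np.corrcoef(pred[:, j], Y[:, j])[0, 1])
    return out



def save_model(model: ExpressionModel, path) -> None:
    """Serialize a model checkpoint (architecture + parameters) to .npz."""
    meta = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in model.config.__dict__.items()},
            "trained": model.trained,
            "arch_hash": model.config.arch_hash()}
    arrays = {f"p{i}": a for i, a in enumerate(model.state())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path) -> ExpressionModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        cfg = meta["config"]
        for k in ("cell_types", "conv_channels"):
            cfg[k] = tuple(cfg[k])
        model = ExpressionModel(ModelConfig(**cfg), seed=0)
        state = [z[f"p{i}"] for i in range(len(z.files) - 1)]
    model.load_state(state)
    model.trained = meta["trained"]
    return model


__all__ += ["save_model", "load_model"]
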