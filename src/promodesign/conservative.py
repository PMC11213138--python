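"""Conservative fine-tuning of design models.

Surrogate models used for input optimization are vulnerable to adversarial
designs: sequences whose predicted differential expression (DE) is high
only because the model extrapolates badly off the training distribution.
Conservative objective training counters this by adding a regularizer to
the fine-tuning loss: at every training step, an inner Adam ascent on
predicted DE (run in the per-position probability simplex, parameterized
through a row-wise softmax) constructs a batch μ_c of would-be adversarial
sequences for each target cell type c, and the loss penalizes the model's
mean predicted DE on μ_c relative to its mean predicted DE on the data
batch:

    L(θ) = Σ_c  E_D[(PE_θc − y_c)²]
         + α Σ_c ( E_{μ_c}[DE_θc] − E_D[DE_θc] )

with α ≥ 0 the conservatism coefficient. The μ samples enter the loss as
constants: gradients do not flow back through the inner ascent trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import ExpressionModel, TrainConfig, de_contrast, fit
from .oracle import SequencePanel
from .seq_core import encode_batch

__all__ = ["InnerAscentConfig", "ConservativeLossReport", "ascend",
           "mu_samples", "conservative_loss", "finetune_conservative",
           "train_alpha_sweep", "DesignModel", "DEFAULT_ALPHAS"]

#: default conservatism sweep
DEFAULT_ALPHAS = (0.0, 0.0003, 0.001, 0.003, 0.01, 0.03)

#: logit scale of the near-vertex relaxed starting point γ·onehot
LOGIT_GAMMA = 5.0


@dataclass(frozen=True)
class InnerAscentConfig:
    """Adam settings for the inner gradient ascent on predicted DE."""

    lr: float = 0.5
    beta1: float = 0.9
    beta2: float = 0.999
    steps: int = 100
    #: max starting sequences per cell type for the μ batches during
    #: training (None = the whole training batch); a minibatch estimate of
    #: E_μ[DE] that keeps the inner-loop cost bounded
    mu_batch: int | None = None

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("inner-ascent learning rate must be positive")
        if self.steps < 0:
            raise ValueError("steps must be >= 0")


@dataclass
class ConservativeLossReport:
    supervised: dict[str, float]
    regularizer: dict[str, float]
    alpha: float
    total: float


def _ascend_rows(model: ExpressionModel, x: np.ndarray,
                 contrast_rows: np.ndarray, cfg: InnerAscentConfig
                 ) -> np.ndarray:
    """Shared ascent core: maximize, per sample i, the contrast
    ``pe_i · contrast_rows[i]`` — rows may target different cell types, so
    the per-cell-type μ batches can run as one stacked optimization."""
    if cfg.steps == 0:
        return x.copy()
    logits = nn.Tensor(LOGIT_GAMMA * x, requires_grad=True)
    opt = nn.Adam([logits], lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)
    A = nn.Tensor(contrast_rows)
    with nn.no_grad_params(model.parameters()):
        for _ in range(cfg.steps):
            opt.zero_grad()
            probs = nn.softmax(logits)
            objective = (model.forward(probs) * A).sum()
            (-objective).backward()
            opt.step()
    z = logits.data.astype(float)
    z -= z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def ascend(model: ExpressionModel, x: np.ndarray, target: str,
           cfg: InnerAscentConfig) -> np.ndarray:
    """T steps of Adam ascent on predicted DE in the probability simplex.

    ``x`` is a batch of (L, 4) matrices (one-hot or simplex points); the
    optimization variable is the per-position logit matrix, initialised as
    γ·x so the relaxed point starts near the given sequence. Returns the
    relaxed probability matrices after the final step (no discretization
    here). Model parameters are untouched. Deterministic.
    """
    x = np.asarray(x, dtype=float)
    a = de_contrast(model.cell_types, target)
    return _ascend_rows(model, x, np.tile(a, (x.shape[0], 1)), cfg)


def mu_samples(model: ExpressionModel, batch: np.ndarray, target: str,
               cfg: InnerAscentConfig) -> np.ndarray:
    """The adversarial distribution μ_c for one training batch: relaxed
    sequences whose predicted DE the current model overestimates."""
    return ascend(model, batch, target, cfg)


def conservative_loss(model: ExpressionModel, batch: np.ndarray,
                      labels: np.ndarray, alpha: float,
                      cfg: InnerAscentConfig,
                      rng: np.random.Generator | None = None,
                      training: bool = False
                      ) -> tuple[nn.Tensor, ConservativeLossReport]:
    """Full conservative fine-tuning objective for one batch.

    Returns the differentiable total loss and a per-cell-type report.
    μ batches are recomputed from the current parameters and treated as
    fixed inputs in the loss.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if labels.shape != (batch.shape[0], len(model.cell_types)):
        raise ValueError("labels must be (n, |C|)")
    pred = model.forward(batch, training=training, rng=rng)
    diff = pred - nn.Tensor(labels)
    total = (diff ** 2).mean(axis=0).sum()
    sup_per_cell = ((pred.data - labels) ** 2).mean(axis=0)
    reg_report: dict[str, float] = {}
    if alpha > 0:
        cts = model.cell_types
        sub = batch if cfg.mu_batch is None else batch[:cfg.mu_batch]
        n = sub.shape[0]
        # one stacked ascent builds μ_c for every cell type at once
        contrasts = np.stack([de_contrast(cts, c) for c in cts])
        rows = np.repeat(contrasts, n, axis=0)
        mu_stack = _ascend_rows(model, np.tile(sub, (len(cts), 1, 1)),
                                rows, cfg)
        # E_{μ_c}[DE_c] from one forward over the stack; E_D[DE_c] reuses
        # the supervised forward's predictions
        de_mu = (model.forward(mu_stack) * nn.Tensor(rows)).sum(
            axis=1).reshape(len(cts), n).mean(axis=1)
        de_data = nn.matmul(pred, nn.Tensor(contrasts.T)).mean(axis=0)
        reg = de_mu - de_data
        total = total + alpha * reg.sum()
        reg_report = {c: float(reg.data[i]) for i, c in enumerate(cts)}
    else:
        reg_report = {c: 0.0 for c in model.cell_types}
    report = ConservativeLossReport(
        supervised={c: float(sup_per_cell[i])
                    for i, c in enumerate(model.cell_types)},
        regularizer=reg_report, alpha=alpha, total=total.item())
    return total, report


def finetune_conservative(model: ExpressionModel, panel: SequencePanel,
                          alpha: float, train_cfg: TrainConfig,
                          inner_cfg: InnerAscentConfig,
                          log: list | None = None) -> ExpressionModel:
    """Fine-tune with the conservative objective; the validation loss used
    for checkpoint selection is the supervised term only, so checkpoints
    are comparable across the α sweep. α=0 is exactly plain fine-tuning.
    """
    if model.cell_types != list(panel.cell_types):
        raise ValueError("model heads do not match the panel cell types")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    X = encode_batch(panel.sequences)
    if alpha == 0:
        return fit(model, X, panel.expression, train_cfg, log=log)

    def step_loss(m, xb, yb, rng):
        total, report = conservative_loss(m, xb, yb, alpha, inner_cfg,
                                          rng=rng, training=True)
        if log is not None:
            log.append(report)
        return total

    return fit(model, X, panel.expression, train_cfg, step_loss=step_loss)


@dataclass
class DesignModel:
    """A fine-tuned design model tagged with its conservatism coefficient."""

    alpha: float
    model: ExpressionModel
    model_id: str
    arch_hash: str = field(default="")

    def __post_init__(self):
        if not self.arch_hash:
            self.arch_hash = self.model.config.arch_hash()


def train_alpha_sweep(model: ExpressionModel, panel: SequencePanel,
                      alphas=DEFAULT_ALPHAS,
                      train_cfg: TrainConfig | None = None,
                      inner_cfg: InnerAscentConfig | None = None
                      ) -> list[DesignModel]:
    """Train one design model per α from the same starting point and the
    same data split; order of ``alphas`` is preserved."""
    alphas = list(alphas)
    if not alphas:
        raise ValueError("alphas must be non-empty")
    if any(a < 0 for a in alphas):
        raise ValueError("alphas must be >= 0")
    train_cfg = train_cfg or TrainConfig()
    inner_cfg = inner_cfg or InnerAscentConfig()
    out = []
    for i, a in enumerate(alphas):
        m = finetune_conservative(model, panel, a, train_cfg, inner_cfg)
        out.append(DesignModel(alpha=a, model=m, model_id=f"design_a{a:g}_{i}"))
    return out
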