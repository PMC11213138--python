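"""Heterogeneous model ensemble for pessimistic candidate scoring.

Design-model predictions across an α sweep are not directly comparable, so
candidates are re-scored by an independently trained ensemble: members
share the pretrained backbone but differ in head type, dropout,
fine-tuning learning rate, and seed, and the fine-tuning data split uses a
seed different from the design models'. The conservative regularizer is
not used here — ensemble members are never used for design.

The pessimistic DE estimate of a candidate is the lower confidence bound
mean − SD over member predictions (population SD, divisor n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .designer import CandidatePool
from .model import (ExpressionModel, TrainConfig, de_contrast, finetune_plain,
                    predict_pe, transfer)
from .oracle import SequencePanel
from .seq_core import encode_batch

logger = logging.getLogger(__name__)

__all__ = ["Ensemble", "PessimisticScore", "build_ensemble",
           "score_candidates", "score_sequences", "filter_candidates"]

_HEAD_CYCLE = ("linear", "hidden", "attnpool")
_DROPOUT_CYCLE = (0.0, 0.1)
_LR_CYCLE = (1e-3, 7e-4)


@dataclass
class Ensemble:
    members: list[ExpressionModel]
    split_seed: int
    member_ids: list[str]

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("an ensemble needs at least 2 members")
        panel = self.members[0].cell_types
        if any(m.cell_types != panel for m in self.members):
            raise ValueError("all members must share the cell-type panel")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def cell_types(self) -> list[str]:
        return self.members[0].cell_types


@dataclass(frozen=True)
class PessimisticScore:
    candidate_id: str
    mean_de: float
    sd_de: float
    lcb_de: float                    # = mean_de - sd_de
    mean_pe: tuple[float, ...]       # ensemble-mean predicted expression per cell

    def __post_init__(self):
        if abs(self.lcb_de - (self.mean_de - self.sd_de)) > 1e-12:
            raise ValueError("lcb_de must equal mean_de - sd_de")


def build_ensemble(pretrained: ExpressionModel, panel: SequencePanel,
                   size: int = 8, base_cfg: TrainConfig | None = None,
                   split_seed: int = 1, design_split_seed: int | None = None,
                   seed: int = 0) -> Ensemble:
    """Fine-tune ``size`` heterogeneous members from the shared pretrained
    backbone. ``split_seed`` must differ from the design models' split seed
    (checked when ``design_split_seed`` is given)."""
    if size < 2:
        raise ValueError("ensemble size must be >= 2")
    if design_split_seed is not None and split_seed == design_split_seed:
        raise ValueError("ensemble split_seed must differ from the design "
                         "models' split seed")
    base_cfg = base_cfg or TrainConfig()
    members, ids = [], []
    for i in range(size):
        head = _HEAD_CYCLE[i % len(_HEAD_CYCLE)]
        dropout = _DROPOUT_CYCLE[(i // len(_HEAD_CYCLE)) % len(_DROPOUT_CYCLE)]
        lr = _LR_CYCLE[i % len(_LR_CYCLE)]
        m = transfer(pretrained, panel.cell_types, head=head, dropout=dropout,
                     seed=seed * 1000 + i)
        cfg = dc_replace(base_cfg, lr=lr, split_seed=split_seed,
                         seed=seed * 1000 + i)
        members.append(finetune_plain(m, panel, cfg))
        ids.append(f"ens{i:02d}_{head}_d{dropout:g}")
    return Ensemble(members=members, split_seed=split_seed, member_ids=ids)


def _member_predictions(e: Ensemble, X: np.ndarray, batch: int = 256
                        ) -> np.ndarray:
    """(members, n, |C|) stacked predictions."""
    out = []
    for m in e.members:
        if not getattr(m, "trained", False):
            raise ValueError("all ensemble members must be trained")
        out.append(np.concatenate([predict_pe(m, X[i:i + batch])
                                   for i in range(0, len(X), batch)]))
    return np.stack(out)


def score_sequences(e: Ensemble, X: np.ndarray, target: str,
                    ids: Sequence[str]) -> list[PessimisticScore]:
    """Pessimistic DE scores for arbitrary encoded sequences."""
    preds = _member_predictions(e, X)                       # (M, n, C)
    a = de_contrast(e.cell_types, target)
    des = preds @ a                                         # (M, n)
    mean = des.mean(axis=0)
    sd = des.std(axis=0)                                    # population SD
    mean_pe = preds.mean(axis=0)                            # (n, C)
    return [PessimisticScore(candidate_id=i, mean_de=float(m), sd_de=float(s),
                             lcb_de=float(m - s), mean_pe=tuple(p))
            for i, m, s, p in zip(ids, mean, sd, mean_pe)]


def score_candidates(e: Ensemble, pool: CandidatePool, target: str
                     ) -> list[PessimisticScore]:
    """One pessimistic score per pool candidate, in pool order."""
    X = encode_batch(pool.sequences())
    return score_sequences(e, X, target, [c.id for c in pool.candidates])


def filter_candidates(scores: Sequence[PessimisticScore], pool: CandidatePool,
                      e: Ensemble, panel: SequencePanel,
                      expression_quantile: float = 0.5
                      ) -> tuple[CandidatePool, list[PessimisticScore]]:
    """Keep candidates with positive ensemble-mean DE AND high predicted
    target-cell expression.

    "High" means at or above the given quantile (default: median) of the
    ensemble-predicted target-cell expression over the fine-tuning panel;
    the threshold quantile is configurable because the selection criterion
    is a policy choice, and it is logged prominently. Order is preserved;
    an empty result is legal and logged as a warning.
    """
    if len(scores) != len(pool):
        raise ValueError("scores are not aligned with the pool")
    if not 0.0 <= expression_quantile <= 1.0:
        raise ValueError("expression_quantile must be in [0, 1]")
    t = e.cell_types.index(pool.target_cell)
    panel_pe = _member_predictions(e, encode_batch(panel.sequences))
    threshold = float(np.quantile(panel_pe.mean(axis=0)[:, t],
                                  expression_quantile))
    logger.info("expression filter: keeping candidates with mean DE > 0 and "
                "predicted %s expression >= %.4f (panel quantile %.2f)",
                pool.target_cell, threshold, expression_quantile)
    kept = [(c, s) for c, s in zip(pool.candidates, scores)
            if s.mean_de > 0 and s.mean_pe[t] >= threshold]
    if not kept:
        logger.warning("candidate filter removed every sequence "
                       "(no positive-DE, high-expression candidates)")
        return CandidatePool([], pool.target_cell), []
    new_pool = CandidatePool([c for c, _ in kept], pool.target_cell)
    return new_pool, [s for _, s in kept]


def write_scores(scores: Sequence[PessimisticScore], e: Ensemble,
                 path: str | Path, kept_ids: set[str] | None = None) -> None:
    rows = []
    for s in scores:
        row = {"id": s.candidate_id, "mean_de": s.mean_de, "sd_de": s.sd_de,
               "lcb_de": s.lcb_de}
        for c, v in zip(e.cell_types, s.mean_pe):
            row[f"mean_pe_{c}"] = v
        if kept_ids is not None:
            row["kept"] = s.candidate_id in kept_ids
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


__all__.append("write_scores")
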