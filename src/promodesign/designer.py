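"""Candidate generation: gradient-ascent design from every starting sequence.

Design reuses the exact inner-ascent procedure used to build the μ
distributions during conservative training — T Adam steps on predicted DE
in the probability simplex starting from the one-hot starting sequence —
followed by hard clipping (per-position argmax) back to discrete DNA.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .conservative import DesignModel, InnerAscentConfig, ascend
from .model import ExpressionModel, predict_de
from .oracle import SequencePanel
from .seq_core import DnaSequence, discretize, encode_batch, write_fasta

__all__ = ["Candidate", "CandidatePool", "design_from", "design_batch",
           "design_pool", "candidate_seed"]


@dataclass(frozen=True)
class Candidate:
    """A designed sequence with full provenance."""

    sequence: DnaSequence
    starting_id: str
    alpha: float
    model_id: str
    predicted_de: float          # design model's predicted DE of the discrete design
    target_cell: str
    seed: int = 0

    @property
    def id(self) -> str:
        return f"{self.model_id}:{self.starting_id}"


@dataclass
class CandidatePool:
    candidates: list[Candidate]
    target_cell: str

    def __post_init__(self):
        keys = [(c.starting_id, c.model_id, c.target_cell) for c in self.candidates]
        if len(set(keys)) != len(keys):
            raise ValueError("(starting_id, model_id, target_cell) must be unique")
        if any(c.target_cell != self.target_cell for c in self.candidates):
            raise ValueError("all candidates must share the pool's target cell")

    def __len__(self) -> int:
        return len(self.candidates)

    def sequences(self) -> list[DnaSequence]:
        return [c.sequence for c in self.candidates]

    def write(self, fasta_path: str | Path, tsv_path: str | Path) -> None:
        named = [DnaSequence(c.id, c.sequence.bases) for c in self.candidates]
        write_fasta(named, fasta_path)
        pd.DataFrame([{
            "id": c.id, "starting_id": c.starting_id, "alpha": c.alpha,
            "model_id": c.model_id, "target_cell": c.target_cell,
            "predicted_de": c.predicted_de, "seed": c.seed,
        } for c in self.candidates]).to_csv(tsv_path, sep="\t", index=False)


def candidate_seed(master_seed: int, model_id: str, starting_id: str) -> int:
    """Stable per-candidate seed: CRC32 hash of the provenance triple,
    kept below 2^31 so downstream generators accept it."""
    return zlib.crc32(f"{master_seed}:{model_id}:{starting_id}".encode()) & 0x7FFFFFFF


def design_batch(model: ExpressionModel, starts: Sequence[DnaSequence],
                 target: str, cfg: InnerAscentConfig) -> list[DnaSequence]:
    """Ascend a batch of starting sequences and hard-clip the results."""
    if not getattr(model, "trained", False):
        raise ValueError("design requires a trained model checkpoint")
    probs = ascend(model, encode_batch(starts), target, cfg)
    return [discretize(probs[i], seq_id=f"design_{s.id}")
            for i, s in enumerate(starts)]


def design_from(model: ExpressionModel, start: DnaSequence, target: str,
                cfg: InnerAscentConfig, seed: int = 0,
                alpha: float = float("nan"), model_id: str = "design"
                ) -> Candidate:
    """Design one candidate from one starting sequence (deterministic given
    the model and inputs; the seed is recorded as provenance)."""
    designed = design_batch(model, [start], target, cfg)[0]
    pde = float(predict_de(model, encode_batch([designed]), target)[0])
    return Candidate(sequence=designed, starting_id=start.id, alpha=alpha,
                     model_id=model_id, predicted_de=pde, target_cell=target,
                     seed=seed)


def design_pool(models: Sequence[DesignModel], panel: SequencePanel,
                target: str, cfg: InnerAscentConfig, master_seed: int = 0,
                chunk: int = 128) -> CandidatePool:
    """One design per (design model, starting sequence): |models|·n
    candidates for the target cell type. Duplicate discrete sequences are
    retained — deduplication is the selection step's concern (the diversity
    term already penalizes them)."""
    models = list(models)
    if not models:
        raise ValueError("need at least one design model")
    if len(panel) == 0:
        raise ValueError("empty starting panel")
    cands: list[Candidate] = []
    for dm in models:
        designed_all: list[DnaSequence] = []
        for i in range(0, len(panel), chunk):
            starts = panel.sequences[i:i + chunk]
            designed_all.extend(design_batch(dm.model, starts, target, cfg))
        X = encode_batch(designed_all)
        pdes = np.concatenate([
            predict_de(dm.model, X[i:i + 256], target)
            for i in range(0, len(X), 256)])
        for s, d, pde in zip(panel.sequences, designed_all, pdes):
            cands.append(Candidate(
                sequence=d, starting_id=s.id, alpha=dm.alpha,
                model_id=dm.model_id, predicted_de=float(pde),
                target_cell=target,
                seed=candidate_seed(master_seed, dm.model_id, s.id)))
    return CandidatePool(cands, target_cell=target)
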