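"""Final batch selection: greedy fitness + diversity maximization.

From the filtered candidate pool, the final validation batch S* of K
sequences maximizes

    sum_{x in S} DE_lcb(x)  +  beta * D(S)

where D(S) is the batch diversity: over every unordered sequence pair, the
normalized Hamming distance plus the normalized Euclidean distance between
6-mer frequency vectors. Exhaustive search is intractable, so S* is built
greedily: at each step the candidate with the best pessimistic score plus
beta times its marginal diversity against the already-chosen set is added.

Diagnostics follow the field's diversity conventions: per-position base
entropy (max 2 bits) and mean pairwise Hamming distance (max L).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .designer import Candidate, CandidatePool
from .ensemble import PessimisticScore
from .oracle import SequencePanel
from .seq_core import (DnaSequence, hamming_norm, kmer_distance_norm,
                       kmer_vector, mean_pairwise_hamming,
                       positionwise_entropy, seqs_to_indices, write_fasta)

logger = logging.getLogger(__name__)

__all__ = ["SelectionConfig", "SelectionResult", "set_diversity",
           "greedy_select", "diversity_report", "DiversityReport",
           "diagnose_training_set", "TrainingSetDiagnosis"]

#: below this fraction of positive-DE training sequences the design problem
#: is flagged as likely too difficult for the available data
POSITIVE_DE_WARN_FRACTION = 0.25


@dataclass(frozen=True)
class SelectionConfig:
    K: int
    beta: float = 0.0
    kmer_k: int = 6

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass
class DiversityReport:
    mean_entropy: float          # bits, in [0, 2]
    mean_hamming: float          # bp, in [0, L]
    entropy_per_position: np.ndarray


@dataclass
class SelectionResult:
    chosen: list[Candidate]
    marginal_gains: list[float]
    objective_value: float
    diagnostics: DiversityReport | None


def set_diversity(seqs: Sequence[DnaSequence], k: int = 6) -> float:
    """D(S): half the sum over ordered pairs of normalized Hamming plus
    normalized k-mer distance — i.e. each unordered pair counted once.
    Zero for sets of size <= 1."""
    seqs = list(seqs)
    total = 0.0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            total += (hamming_norm(seqs[i], seqs[j])
                      + kmer_distance_norm(seqs[i], seqs[j], k))
    return total


def _pair_dist(idx: np.ndarray, kvecs: np.ndarray, i: int, j: int) -> float:
    h = float((idx[i] != idx[j]).mean())
    kd = float(np.linalg.norm(kvecs[i] - kvecs[j])) / np.sqrt(2.0)
    return h + kd


def greedy_select(pool: CandidatePool, scores: Sequence[PessimisticScore],
                  cfg: SelectionConfig) -> SelectionResult:
    """Greedy maximization of sum(lcb) + beta * D(S).

    Each step adds the candidate maximizing lcb(x) + beta * D(S' ∪ {x});
    since D(S') is constant within a step, the marginal diversity against
    S' is what is compared. Ties break toward the higher lcb, then the
    lexicographically smaller candidate id. Deterministic. Pairwise
    distances to chosen sequences are computed incrementally, giving
    O(K·|pool|) distance evaluations.
    """
    n = len(pool)
    if n < cfg.K:
        raise ValueError(f"pool has {n} candidates, fewer than K={cfg.K}")
    if len(scores) != n:
        raise ValueError("scores are not aligned with the pool")
    idx = seqs_to_indices(pool.sequences())
    kvecs = np.stack([kmer_vector(s, cfg.kmer_k) for s in pool.sequences()])
    lcb = np.array([s.lcb_de for s in scores])
    ids = [c.id for c in pool.candidates]

    chosen: list[int] = []
    gains: list[float] = []
    div_sum = 0.0                         # D of the chosen set
    marg = np.zeros(n)                    # sum of distances to chosen set
    available = set(range(n))
    for _ in range(cfg.K):
        best = None
        for i in available:
            key = (lcb[i] + cfg.beta * marg[i], lcb[i], _NegStr(ids[i]))
            if best is None or key > best[0]:
                best = (key, i)
        (gain, _, _), pick = best
        chosen.append(pick)
        gains.append(float(gain))
        div_sum += marg[pick]
        available.discard(pick)
        for i in available:
            marg[i] += _pair_dist(idx, kvecs, i, pick)
    objective = float(lcb[chosen].sum() + cfg.beta * div_sum)
    chosen_cands = [pool.candidates[i] for i in chosen]
    diagnostics = (diversity_report([c.sequence for c in chosen_cands])
                   if cfg.K >= 2 else None)
    if diagnostics is not None:
        L = len(chosen_cands[0].sequence)
        if diagnostics.mean_entropy < 1.0 or diagnostics.mean_hamming < L / 4:
            logger.warning(
                "selected batch has low diversity (entropy %.2f bits, "
                "Hamming %.1f bp); consider increasing beta",
                diagnostics.mean_entropy, diagnostics.mean_hamming)
    return SelectionResult(chosen=chosen_cands, marginal_gains=gains,
                           objective_value=objective, diagnostics=diagnostics)


class _NegStr(str):
    """String with reversed ordering, so max() prefers the smaller id."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def diversity_report(seqs: Sequence[DnaSequence]) -> DiversityReport:
    """Mean per-position base entropy and mean pairwise Hamming distance."""
    if len(seqs) < 2:
        raise ValueError("diversity report needs at least 2 sequences")
    ent = positionwise_entropy(seqs)
    return DiversityReport(mean_entropy=float(ent.mean()),
                           mean_hamming=mean_pairwise_hamming(seqs),
                           entropy_per_position=ent)


@dataclass
class TrainingSetDiagnosis:
    target_cell: str
    positive_de_fraction: float
    warning: bool


def diagnose_training_set(panel: SequencePanel, target: str
                          ) -> TrainingSetDiagnosis:
    """Fraction of training sequences with measured DE > 0 for the target;
    warns when fewer than 25% — a sign the design problem may be too hard
    for the available data."""
    de = panel.measured_de(target)
    frac = float((de > 0).mean())
    warn = frac < POSITIVE_DE_WARN_FRACTION
    if warn:
        logger.warning(
            "only %.1f%% of training sequences have positive measured DE for "
            "%s (< %.0f%%); the design problem may be too difficult",
            100 * frac, target, 100 * POSITIVE_DE_WARN_FRACTION)
    return TrainingSetDiagnosis(target_cell=target, positive_de_fraction=frac,
                                warning=warn)


def write_selection(result: SelectionResult, fasta_path: str | Path,
                    tsv_path: str | Path) -> None:
    write_fasta([DnaSequence(c.id, c.sequence.bases) for c in result.chosen],
                fasta_path)
    pd.DataFrame([{
        "rank": r, "id": c.id, "starting_id": c.starting_id,
        "alpha": c.alpha, "model_id": c.model_id,
        "marginal_gain": g,
    } for r, (c, g) in enumerate(zip(result.chosen, result.marginal_gains))]
    ).to_csv(tsv_path, sep="\t", index=False)


__all__.append("write_selection")
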