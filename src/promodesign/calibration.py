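"""Cross-batch calibration of DE via percentile scores on a common set.

DE values measured in different experimental batches are not directly
comparable (batch effects, different conditions). A common set of
sequences measured in both batches anchors the comparison: each value is
converted to its percentile among the common set's values from its own
batch, and a designed sequence counts as an improvement when its
percentile (batch B) strictly exceeds its starting sequence's percentile
(batch A). The calibration is only trusted when the common set's DE ranks
are concordant between batches (Spearman rho at or above a configurable
floor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["CommonSet", "ImprovementReport", "percentile_score",
           "concordance_check", "improvement_report", "percent_gain_best"]

MIN_COMMON_SET = 20
SPEARMAN_FLOOR = 0.8


@dataclass
class CommonSet:
    """Ids of sequences with DE measured in both batches for one target."""

    ids: list[str]

    def __post_init__(self):
        if len(self.ids) < MIN_COMMON_SET:
            raise ValueError(
                f"common set needs >= {MIN_COMMON_SET} members, got {len(self.ids)}")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("common-set ids must be unique")


def percentile_score(value: float, reference: Sequence[float]) -> float:
    """Midrank percentile of ``value`` among ``reference``, in [0, 100]:
    100 · (#strictly below + ½·#equal) / n. Monotone non-decreasing in
    ``value``."""
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("reference must be non-empty")
    below = float((ref < value).sum())
    equal = float((ref == value).sum())
    return 100.0 * (below + 0.5 * equal) / ref.size


def concordance_check(common: CommonSet, batch_a: Mapping[str, float],
                      batch_b: Mapping[str, float],
                      floor: float = SPEARMAN_FLOOR) -> float:
    """Spearman rank correlation of the common set's DE between batches
    (ties handled by average ranks). Warns when below the floor — the
    percentile calibration is then not trustworthy."""
    missing = [i for i in common.ids if i not in batch_a or i not in batch_b]
    if missing:
        raise KeyError(f"common-set ids missing from a batch: {missing[:5]}")
    a = np.array([batch_a[i] for i in common.ids])
    b = np.array([batch_b[i] for i in common.ids])
    rho = float(stats.spearmanr(a, b).statistic)
    if rho < floor:
        logger.warning("common-set Spearman rho=%.3f below floor %.2f; "
                       "cross-batch percentiles may be unreliable", rho, floor)
    return rho


@dataclass
class PairResult:
    starting_id: str
    designed_id: str
    starting_percentile: float
    designed_percentile: float
    improved: bool


@dataclass
class ImprovementReport:
    pairs: list[PairResult]
    fraction_improved: float
    spearman_rho: float
    dropped_pairs: int = 0
    per_pair: dict = field(default_factory=dict)


def improvement_report(pairs: Sequence[tuple[str, str]], common: CommonSet,
                       batch_a: Mapping[str, float],
                       batch_b: Mapping[str, float]) -> ImprovementReport:
    """Per-pair percentile comparison of (starting id in batch A, designed
    id in batch B); unresolvable pairs are dropped and counted."""
    rho = concordance_check(common, batch_a, batch_b)
    ref_a = [batch_a[i] for i in common.ids]
    ref_b = [batch_b[i] for i in common.ids]
    results: list[PairResult] = []
    dropped = 0
    for start_id, design_id in pairs:
        if start_id not in batch_a or design_id not in batch_b:
            dropped += 1
            continue
        ps = percentile_score(batch_a[start_id], ref_a)
        pd_ = percentile_score(batch_b[design_id], ref_b)
        results.append(PairResult(start_id, design_id, ps, pd_, pd_ > ps))
    frac = (sum(r.improved for r in results) / len(results)) if results else 0.0
    return ImprovementReport(pairs=results, fraction_improved=float(frac),
                             spearman_rho=rho, dropped_pairs=dropped)


def percent_gain_best(best_designed_de: float, best_start_de: float) -> float:
    """Percent gain of the best designed DE over the best starting DE,
    100·(designed − start)/start, reported to 2 decimals. A negative
    baseline flips the sign interpretation and is logged; a zero baseline
    is rejected."""
    if best_start_de == 0:
        raise ValueError("best starting DE is zero; percent gain undefined")
    if best_start_de < 0:
        logger.warning("best starting DE is negative (%.4f); percent gain "
                       "sign is not meaningful", best_start_de)
    return round(100.0 * (best_designed_de - best_start_de) / best_start_de, 2)
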