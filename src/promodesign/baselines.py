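"""Motif-tiling baseline.

The traditional alternative to model-based design: mine k-mers associated
with high DE from the training panel, then implant them into sequences
that already have high DE. Serves as a head-to-head comparator for the
gradient-ascent designs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .oracle import SequencePanel
from .seq_core import BASE_INDEX, ALPHABET, DnaSequence

__all__ = ["MotifCatalog", "mine_de_motifs", "tile_motifs"]


@dataclass
class MotifCatalog:
    """Consensus k-mers ranked by association with high DE in one cell type."""

    target_cell: str
    motifs: list[tuple[str, float]]      # (consensus, log-odds score)

    def __post_init__(self):
        if not self.motifs:
            raise ValueError("catalog must contain at least one motif")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"target_cell": self.target_cell,
             "motifs": [{"consensus": c, "score": s} for c, s in self.motifs]},
            indent=1))


def _kmer_presence(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def mine_de_motifs(panel: SequencePanel, target: str, k: int = 8,
                   top_fraction: float = 0.1, n_keep: int = 10
                   ) -> MotifCatalog:
    """Rank k-mers by log odds of presence in the highest-DE sequences
    (top ``top_fraction`` by measured DE) versus the rest; keep the top
    ``n_keep``. Haldane-corrected (+0.5) counts keep the odds finite."""
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0, 1)")
    de = panel.measured_de(target)
    if np.ptp(de) == 0:
        raise ValueError("degenerate panel: all DE values equal")
    n_fg = max(1, int(round(top_fraction * len(panel))))
    order = np.argsort(-de)
    fg_idx, bg_idx = order[:n_fg], order[n_fg:]
    fg_counts: dict[str, int] = {}
    bg_counts: dict[str, int] = {}
    for i in fg_idx:
        for km in _kmer_presence(panel.sequences[i].bases, k):
            fg_counts[km] = fg_counts.get(km, 0) + 1
    for i in bg_idx:
        for km in _kmer_presence(panel.sequences[i].bases, k):
            bg_counts[km] = bg_counts.get(km, 0) + 1
    n_fg_f, n_bg_f = float(len(fg_idx)), float(len(bg_idx))
    scores = []
    for km in set(fg_counts) | set(bg_counts):
        f = fg_counts.get(km, 0)
        b = bg_counts.get(km, 0)
        lo = (np.log((f + 0.5) / (n_fg_f - f + 0.5))
              - np.log((b + 0.5) / (n_bg_f - b + 0.5)))
        scores.append((km, float(lo)))
    scores.sort(key=lambda t: (-t[1], t[0]))
    return MotifCatalog(target_cell=target, motifs=scores[:n_keep])


def tile_motifs(start: DnaSequence, catalog: MotifCatalog,
                n_insertions: int, seed: int = 0) -> DnaSequence:
    """Overwrite ``n_insertions`` catalog motifs (sampled by rank weight) at
    uniform non-overlapping positions. Overwriting, not inserting, keeps the
    sequence length fixed at L. Reproducible under the seed; if a
    non-overlapping position cannot be found in 100 draws the placement is
    skipped."""
    L = len(start)
    widths = [len(c) for c, _ in catalog.motifs]
    if n_insertions < 0:
        raise ValueError("n_insertions must be >= 0")
    if n_insertions and n_insertions * max(widths) > L // 2:
        raise ValueError("requested insertions would overwrite more than "
                         "half the sequence")
    if n_insertions == 0:
        return start
    rng = np.random.default_rng(seed)
    bases = list(start.bases)
    occupied: list[tuple[int, int]] = []
    # favour the strongest motifs but keep some variety
    weights = np.array([max(s, 0.0) + 1.0 for _, s in catalog.motifs])
    weights = weights / weights.sum()
    for _ in range(n_insertions):
        m = int(rng.choice(len(catalog.motifs), p=weights))
        cons = catalog.motifs[m][0]
        w = len(cons)
        for _attempt in range(100):
            pos = int(rng.integers(0, L - w + 1))
            if all(pos + w <= a or pos >= b for a, b in occupied):
                bases[pos:pos + w] = cons
                occupied.append((pos, pos + w))
                break
    return DnaSequence(f"tiled_{start.id}", "".join(bases))
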