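"""Core DNA sequence representations, encodings, distances, and entropy.

Every other module speaks in terms of these primitives. The base column
order is fixed globally as A, C, G, T; all one-hot encodings, probability
matrices, and argmax tie-breaks use this order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

__all__ = [
    "ALPHABET", "BASE_INDEX", "DnaSequence", "RelaxedSequence",
    "encode_one_hot", "encode_batch", "decode_indices", "discretize",
    "hamming_norm", "kmer_vector", "kmer_distance_norm",
    "positionwise_entropy", "mean_pairwise_hamming",
    "read_fasta", "write_fasta", "read_sequence_table", "seqs_to_indices",
]


@dataclass(frozen=True)
class DnaSequence:
    """A fixed-length promoter sequence over the strict A/C/G/T alphabet."""

    id: str
    bases: str

    def __post_init__(self):
        for pos, ch in enumerate(self.bases):
            if ch not in BASE_INDEX:
                raise ValueError(
                    f"sequence {self.id!r}: invalid base {ch!r} at position {pos}")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class RelaxedSequence:
    """A point in the per-position probability simplex over A/C/G/T.

    ``probs`` is the softmax of ``logits`` row by row — the continuous
    optimization variable used for gradient ascent in sequence space.
    """

    logits: np.ndarray  # (L, 4)

    @property
    def probs(self) -> np.ndarray:
        z = self.logits - self.logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


def encode_one_hot(seq: DnaSequence) -> np.ndarray:
    """One-hot encode to an (L, 4) 0/1 matrix, columns ordered A,C,G,T."""
    idx = np.fromiter((BASE_INDEX[b] for b in seq.bases), dtype=np.intp,
                      count=len(seq.bases))
    out = np.zeros((len(seq.bases), 4))
    out[np.arange(len(idx)), idx] = 1.0
    return out


def seqs_to_indices(seqs: Sequence[DnaSequence]) -> np.ndarray:
    """(n, L) integer base indices for a list of equal-length sequences."""
    if not seqs:
        raise ValueError("empty sequence list")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must have equal length")
    flat = "".join(s.bases for s in seqs)
    lut = np.full(128, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
    return lut[np.frombuffer(flat.encode(), dtype=np.uint8)].reshape(len(seqs), L).astype(np.intp)


def encode_batch(seqs: Sequence[DnaSequence]) -> np.ndarray:
    """Stack one-hot encodings into an (n, L, 4) array."""
    idx = seqs_to_indices(seqs)
    out = np.zeros(idx.shape + (4,))
    np.put_along_axis(out, idx[:, :, None], 1.0, axis=2)
    return out


def decode_indices(idx: np.ndarray, seq_id: str = "seq") -> DnaSequence:
    return DnaSequence(seq_id, "".join(ALPHABET[i] for i in idx))


def discretize(probs: np.ndarray, seq_id: str = "design") -> DnaSequence:
    """Hard-clip an (L, 4) probability matrix to the per-position argmax base.

    Ties break toward the alphabetically first base (numpy argmax returns the
    first maximal column, and columns are ordered A,C,G,T).
    """
    probs = np.asarray(probs)
    if probs.ndim != 2 or probs.shape[1] != 4:
        raise ValueError("expected an (L, 4) probability matrix")
    return decode_indices(probs.argmax(axis=1), seq_id)


def hamming_norm(a: DnaSequence, b: DnaSequence) -> float:
    """Normalized Hamming distance: mismatched positions / L, in [0, 1]."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a.bases, b.bases)) / len(a)


def kmer_vector(seq: DnaSequence, k: int = 6) -> np.ndarray:
    """Frequency vector over all 4^k k-mers (overlapping windows, forward
    strand), summing to 1."""
    L = len(seq)
    if L < k:
        raise ValueError(f"sequence length {L} < k={k}")
    idx = np.fromiter((BASE_INDEX[b] for b in seq.bases), dtype=np.int64, count=L)
    powers = 4 ** np.arange(k - 1, -1, -1)
    codes = np.lib.stride_tricks.sliding_window_view(idx, k) @ powers
    vec = np.bincount(codes, minlength=4 ** k).astype(float)
    return vec / vec.sum()


def kmer_distance_norm(a: DnaSequence, b: DnaSequence, k: int = 6) -> float:
    """Euclidean distance between k-mer frequency vectors, divided by √2.

    √2 is the maximum possible distance between two frequency vectors
    (attained by disjoint one-hot vectors), so the result lies in [0, 1].
    """
    d = float(np.linalg.norm(kmer_vector(a, k) - kmer_vector(b, k)))
    return d / np.sqrt(2.0)


def positionwise_entropy(seqs: Sequence[DnaSequence]) -> np.ndarray:
    """Shannon entropy (bits) of base usage at each position, in [0, 2]."""
    if not seqs:
        raise ValueError("need at least one sequence")
    idx = seqs_to_indices(seqs)
    n, L = idx.shape
    counts = np.zeros((L, 4))
    for b in range(4):
        counts[:, b] = (idx == b).sum(axis=0)
    p = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=1)


def mean_pairwise_hamming(seqs: Sequence[DnaSequence]) -> float:
    """Mean unnormalized Hamming distance over all unordered pairs, in [0, L].

    Computed from per-position base counts, which is exact and O(nL) rather
    than O(n^2 L).
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    idx = seqs_to_indices(seqs)
    n = idx.shape[0]
    mism = 0.0
    for b in range(4):
        cnt = (idx == b).sum(axis=0)
        mism += (cnt * (n - cnt)).sum()
    # each unordered mismatching pair counted twice (once per base)
    return mism / 2.0 / (n * (n - 1) / 2.0)


# ----------------------------------------------------------------------- #
# I/O
# ----------------------------------------------------------------------- #

def read_fasta(path: str | Path, expected_length: int | None = None
               ) -> list[DnaSequence]:
    seqs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = DnaSequence(rec.id, str(rec.seq).upper())
        if expected_length is not None and len(s) != expected_length:
            raise ValueError(
                f"sequence {s.id!r} has length {len(s)}, expected {expected_length}")
        seqs.append(s)
    return seqs


def write_fasta(seqs: Iterable[DnaSequence], path: str | Path) -> None:
    """Write sequences as FASTA wrapped at 80 columns."""
    from Bio.SeqIO.FastaIO import FastaWriter
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=80).write_file(records)


def read_sequence_table(path: str | Path, expected_length: int | None = None
                        ) -> tuple[list[DnaSequence], pd.DataFrame]:
    """Read a TSV of (id, sequence, one numeric column per cell type).

    Returns the sequences and a DataFrame of the expression columns indexed
    by sequence id.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sequence": str})
    if "id" not in df.columns or "sequence" not in df.columns:
        raise ValueError("table must have 'id' and 'sequence' columns")
    seqs = [DnaSequence(r.id, r.sequence.upper())
            for r in df.itertuples(index=False)]
    if expected_length is not None:
        for s in seqs:
            if len(s) != expected_length:
                raise ValueError(
                    f"sequence {s.id!r} has length {len(s)}, expected {expected_length}")
    expr = df.drop(columns=["sequence"]).set_index("id")
    return seqs, expr.astype(float)
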