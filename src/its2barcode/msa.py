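"""Progressive multiple alignment for barcode libraries.

A deliberately simple, fully deterministic aligner: a guide tree from
k-mer sharing distances (k = 6), then profile–profile global
Needleman–Wunsch merges with affine gaps (match +1, mismatch −1, gap
open −2, gap extend −0.5).  Barcode flanks are conserved and sequences
are short, so this recovers near-reference alignments; externally
computed alignments can be supplied anywhere an ``Alignment`` is
accepted, bypassing this module entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .annotate import encode
from .records import SequenceRecord, read_fasta, write_fasta

GAP_OPEN = -2.0
GAP_EXTEND = -0.5
# match +1 / mismatch -1 over ACGT
_SUBST = 2.0 * np.eye(4) - 1.0


@dataclass
class Alignment:
    """Equal-length gapped rows over {A,C,G,T,-,ambiguity}."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids must be unique")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(widths)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, specimen_id: str) -> str:
        return self.rows[self.ids.index(specimen_id)]

    def encoded(self) -> np.ndarray:
        """(n_rows, n_cols) int8 matrix; A..T → 0..3, gap/ambiguity → 4."""
        return np.stack([encode(r) for r in self.rows])

    def subset(self, ids: Sequence[str]) -> "Alignment":
        index = {s: i for i, s in enumerate(self.ids)}
        return Alignment(list(ids), [self.rows[index[s]] for s in ids])

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        """Bootstrap replicate: columns drawn with replacement."""
        cols = rng.integers(0, self.n_cols, size=self.n_cols)
        mat = np.array([list(r) for r in self.rows])
        return Alignment(list(self.ids), ["".join(row) for row in mat[:, cols]])

    def write_fasta(self, path: str | Path) -> None:
        write_fasta(
            (SequenceRecord(i, r) for i, r in zip(self.ids, self.rows)), path
        )

    @classmethod
    def read_fasta(cls, path: str | Path) -> "Alignment":
        recs = read_fasta(path)
        return cls([r.specimen_id for r in recs], [r.sequence for r in recs])


# ---------------------------------------------------------------------------
# pairwise / profile-profile Needleman-Wunsch (affine gaps)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _nw_affine(S: np.ndarray, gap_open: float, gap_ext: float):
    """Global affine-gap DP over a precomputed column-score matrix.

    Returns (steps, score) where steps[k] is 0 = consume both, 1 =
    consume row-profile column only (gap in the other), 2 = consume
    column-profile column only.  Ties prefer the diagonal, then the
    vertical state — a fixed order that makes the aligner deterministic.
    """
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in B (consume A)
    Y = np.full((n + 1, m + 1), NEG)  # gap in A (consume B)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_ext
        pX[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_ext
        pY[0, j] = 2 if j > 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = M[i - 1, j - 1]
            arg = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                arg = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                arg = 2
            M[i, j] = best + S[i - 1, j - 1]
            pM[i, j] = arg
            a = M[i - 1, j] + gap_open
            b = X[i - 1, j] + gap_ext
            if a >= b:
                X[i, j] = a
                pX[i, j] = 0
            else:
                X[i, j] = b
                pX[i, j] = 1
            a = M[i, j - 1] + gap_open
            b = Y[i, j - 1] + gap_ext
            if a >= b:
                Y[i, j] = a
                pY[i, j] = 0
            else:
                Y[i, j] = b
                pY[i, j] = 2
    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    steps = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        steps[k] = state
        if state == 0:
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = pX[i, j]
            i -= 1
        else:
            state = pY[i, j]
            j -= 1
        k += 1
    return steps[:k][::-1], score


def _profile(rows: list[str]) -> np.ndarray:
    """(n_cols, 4) residue counts; gaps and ambiguity contribute nothing."""
    enc = np.stack([encode(r) for r in rows])
    counts = np.zeros((enc.shape[1], 4))
    for b in range(4):
        counts[:, b] = (enc == b).sum(axis=0)
    return counts


def _merge(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], float]:
    ca, cb = _profile(rows_a), _profile(rows_b)
    na, nb = len(rows_a), len(rows_b)
    # expected pair score between columns; gap-residue pairs score 0
    S = (ca @ _SUBST @ cb.T) / (na * nb)
    steps, score = _nw_affine(S, GAP_OPEN, GAP_EXTEND)
    ai, bi = [], []
    i = j = 0
    for s in steps:
        if s == 0:
            ai.append(i)
            bi.append(j)
            i += 1
            j += 1
        elif s == 1:
            ai.append(i)
            bi.append(-1)
            i += 1
        else:
            ai.append(-1)
            bi.append(j)
            j += 1
    new_a = ["".join(r[k] if k >= 0 else "-" for k in ai) for r in rows_a]
    new_b = ["".join(r[k] if k >= 0 else "-" for k in bi) for r in rows_b]
    return new_a + new_b, float(score)


def pairwise_align(seq_a: str, seq_b: str) -> tuple[str, str, float]:
    """Global affine-gap alignment of two sequences (the aligner's own
    scoring); returns the two gapped rows and the score."""
    rows, score = _merge([seq_a], [seq_b])
    return rows[0], rows[1], score


# ---------------------------------------------------------------------------
# guide tree and progressive merge
# ---------------------------------------------------------------------------

def kmer_distance_matrix(seqs: Sequence[str], k: int = 6) -> np.ndarray:
    """1 − fraction of shared distinct k-mers (relative to the smaller set)."""
    k_eff = max(1, min(k, min(len(s) for s in seqs)))
    sets = [
        {s[i : i + k_eff] for i in range(len(s) - k_eff + 1)} for s in seqs
    ]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j]))
            f = len(sets[i] & sets[j]) / denom if denom else 0.0
            d[i, j] = d[j, i] = 1.0 - f
    return d


def progressive_align(records: Sequence[SequenceRecord], k: int = 6) -> Alignment:
    """Align a library progressively along a k-mer-distance guide tree."""
    if len(records) == 0:
        raise ValueError("no records to align")
    if len(records) == 1:
        return Alignment([records[0].specimen_id], [records[0].sequence])
    ids = [r.specimen_id for r in records]
    seqs = [r.sequence for r in records]
    dmat = kmer_distance_matrix(seqs, k=k)
    Z = linkage(squareform(dmat, checks=False), method="average")
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seqs[i]]) for i in range(len(records))
    }
    nxt = len(records)
    for a, b, _, _ in Z:
        ids_a, rows_a = clusters.pop(int(a))
        ids_b, rows_b = clusters.pop(int(b))
        merged, _ = _merge(rows_a, rows_b)
        clusters[nxt] = (ids_a + ids_b, merged)
        nxt += 1
    (final_ids, final_rows) = clusters.popitem()[1]
    aln = Alignment(final_ids, final_rows)
    return aln.subset(ids)  # restore input order
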