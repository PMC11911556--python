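"""Positional and compositional k-mer descriptors of RNA windows.

For k = 1, 2, 3 (mono-, di-, tri-nucleotides, overlapping, stride 1):

* PRIM — the position relative incidence matrix: for each ordered
  k-mer pair (i, j), the sum of position offsets of every occurrence
  of j that falls strictly after the first occurrence of i.
* RPRIM — the PRIM of the reversed sequence (plain reversal; RNA
  windows are single-stranded, so no complementation).
* FV — overlapping k-mer occurrence counts.
* AAPIV — per k-mer, the sum of the 1-based start positions of its
  occurrences (the accumulative absolute position incidence vector).
* RAAPIV — the AAPIV of the reversed sequence.

K-mers are ordered lexicographically with A < C < G < U throughout.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np

from .moments import MomentConfig, moment_descriptor
from .seq_io import ALPHABET, SequenceWindow


@lru_cache(maxsize=8)
def kmer_alphabet(k: int) -> tuple[str, ...]:
    """All 4^k k-mers over {A, C, G, U}, lexicographic (A < C < G < U)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return tuple("".join(p) for p in product(ALPHABET, repeat=k))


def _as_sequence(window: SequenceWindow | str) -> str:
    return window.sequence if isinstance(window, SequenceWindow) else window


def kmer_positions(
    window: SequenceWindow | str, k: int
) -> dict[str, list[int]]:
    """1-based start positions of every overlapping k-mer occurrence."""
    seq = _as_sequence(window)
    positions: dict[str, list[int]] = {kmer: [] for kmer in kmer_alphabet(k)}
    for start in range(len(seq) - k + 1):
        positions[seq[start:start + k]].append(start + 1)
    return positions


def prim(window: SequenceWindow | str, k: int) -> np.ndarray:
    """Position relative incidence matrix, 4^k x 4^k.

    Entry [i][j] = sum over occurrences p of k-mer j with p > f_i of
    (p - f_i), where f_i is the position of the first occurrence of
    k-mer i. Rows of absent k-mers are zero.
    """
    alphabet = kmer_alphabet(k)
    positions = kmer_positions(window, k)
    size = len(alphabet)
    out = np.zeros((size, size), dtype=np.int64)
    rows = [i for i, kmer in enumerate(alphabet) if positions[kmer]]
    if not rows:
        return out
    firsts = np.array(
        [positions[alphabet[i]][0] for i in rows], dtype=np.int64
    )
    for j, kmer_j in enumerate(alphabet):
        pj = positions[kmer_j]
        if not pj:
            continue
        pj_arr = np.array(pj, dtype=np.int64)  # ascending by construction
        prefix = np.concatenate(([0], np.cumsum(pj_arr)))
        idx = np.searchsorted(pj_arr, firsts, side="right")
        # sum of (p - first) over occurrences p of j with p > first
        out[rows, j] = (prefix[-1] - prefix[idx]) - firsts * (pj_arr.size - idx)
    return out


def rprim(window: SequenceWindow | str, k: int) -> np.ndarray:
    """PRIM of the reversed sequence."""
    return prim(_as_sequence(window)[::-1], k)


def frequency_vector(window: SequenceWindow | str, k: int) -> np.ndarray:
    """Overlapping k-mer occurrence counts, length 4^k."""
    positions = kmer_positions(window, k)
    return np.array(
        [len(positions[kmer]) for kmer in kmer_alphabet(k)], dtype=np.int64
    )


def aapiv(window: SequenceWindow | str, k: int) -> np.ndarray:
    """Accumulated 1-based occurrence positions per k-mer, length 4^k."""
    positions = kmer_positions(window, k)
    return np.array(
        [sum(positions[kmer]) for kmer in kmer_alphabet(k)], dtype=np.int64
    )


def raapiv(window: SequenceWindow | str, k: int) -> np.ndarray:
    """AAPIV of the reversed sequence."""
    return aapiv(_as_sequence(window)[::-1], k)


def reduce_matrix(
    matrix: np.ndarray, cfg: MomentConfig = MomentConfig()
) -> np.ndarray:
    """Reduce a square incidence matrix to its 30 moment coefficients."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("reduce_matrix requires a square matrix")
    return moment_descriptor(matrix, cfg).values
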