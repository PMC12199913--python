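"""Raw (pre-moment) k-mer representations of a sequence window.

For k-mer orders 1, 2 and 3 (overlapping tokens, step 1) this module
builds the building blocks of the position/composition encoding:

* frequency vector — occurrence counts of every k-mer;
* AAPIV / RAAPIV — accumulative absolute position incidence vectors:
  per k-mer sums of 1-based occurrence start positions, on the forward
  and reversed sequence respectively;
* PRIM / RPRIM — position-relative incidence matrices: square matrices
  over k-mers whose entry (i, j) accumulates the offsets of every
  occurrence of k-mer j relative to the first occurrence of k-mer i;
* a near-square 2-D layout of the integer-coded k-mer sequence, the
  input to the 2-D moment transforms.

K-mers are ordered lexicographically with A < C < G < U, i.e. as base-4
numerals with A=0, C=1, G=2, U=3.  All functions accept either a
:class:`~omsite.sequence_io.SequenceWindow` or a plain residue string
(the latter of any length >= k, handy for toy oracles in tests).
"""

from __future__ import annotations

import math
from itertools import product
from typing import Union

import numpy as np

from .sequence_io import ALPHABET, SequenceWindow, ValidationError

K_ORDERS = (1, 2, 3)
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

SeqLike = Union[SequenceWindow, str]


def _residues(seq: SeqLike) -> str:
    return seq.residues if isinstance(seq, SequenceWindow) else seq


def kmer_index(kmer: str) -> int:
    """Lexicographic rank of a k-mer (k in 1..3), A<C<G<U."""
    if not 1 <= len(kmer) <= 3:
        raise ValidationError(f"k-mer length must be 1..3, got {kmer!r}")
    idx = 0
    for ch in kmer:
        if ch not in _BASE_INDEX:
            raise ValidationError(f"invalid k-mer character in {kmer!r}")
        idx = idx * 4 + _BASE_INDEX[ch]
    return idx


def all_kmers(k: int) -> list[str]:
    """All 4^k k-mers in canonical (index) order."""
    return ["".join(p) for p in product(ALPHABET, repeat=k)]


def _codes(seq: SeqLike, k: int) -> np.ndarray:
    """Integer codes (0 .. 4^k-1) of the overlapping k-mer tokens."""
    s = _residues(seq)
    if k not in K_ORDERS:
        raise ValidationError(f"k must be in {K_ORDERS}, got {k}")
    if len(s) < k:
        raise ValidationError(f"sequence shorter than k={k}")
    base = np.fromiter((_BASE_INDEX[c] for c in s), dtype=np.int64, count=len(s))
    codes = base[: len(s) - k + 1].copy()
    for j in range(1, k):
        codes = codes * 4 + base[j : len(s) - k + 1 + j]
    return codes


def frequency_vector(seq: SeqLike) -> np.ndarray:
    """Counts of every overlapping k-mer, k=1..3, as one 84-vector.

    Layout: [mono 4 | di 16 | tri 64], each block in canonical k-mer
    order.  For a 41-mer the blocks sum to 41, 40 and 39 (the token
    counts of the three orders).
    """
    return np.concatenate(
        [np.bincount(_codes(seq, k), minlength=4**k) for k in K_ORDERS]
    )


def aapiv(seq: SeqLike) -> np.ndarray:
    """Accumulative absolute position incidence vector (forward).

    For each k-mer, the sum of the 1-based start positions of its
    occurrences; 84 entries in the [mono|di|tri] layout.  The mono block
    always totals L(L+1)/2 (861 for 41-mers).
    """
    parts = []
    for k in K_ORDERS:
        codes = _codes(seq, k)
        positions = np.arange(1, len(codes) + 1, dtype=np.int64)
        parts.append(np.bincount(codes, weights=positions, minlength=4**k))
    return np.concatenate(parts).astype(np.int64)


def raapiv(seq: SeqLike) -> np.ndarray:
    """Reverse accumulative vector: aapiv of the reversed sequence."""
    return aapiv(_residues(seq)[::-1])


def prim(seq: SeqLike, k: int) -> np.ndarray:
    """Position-relative incidence matrix (forward), side 4^k.

    entry[i, j] = sum over occurrences of k-mer j at start position p of
    (p - first_position(i)), positions 1-based.  Rows of absent k-mers
    are identically zero; offsets may be negative.

    With S_j the position-sum and c_j the count of k-mer j, the row for
    a present k-mer i is S - first_i * c, which is how it is computed.
    """
    codes = _codes(seq, k)
    size = 4**k
    positions = np.arange(1, len(codes) + 1, dtype=np.int64)
    counts = np.bincount(codes, minlength=size)
    pos_sums = np.bincount(codes, weights=positions, minlength=size).astype(np.int64)
    matrix = np.zeros((size, size), dtype=np.int64)
    present = np.flatnonzero(counts)
    for i in present:
        first_i = int(positions[codes == i][0])
        matrix[i, :] = pos_sums - first_i * counts
    return matrix


def rprim(seq: SeqLike, k: int) -> np.ndarray:
    """Reverse-order incidence matrix: prim of the reversed sequence."""
    return prim(_residues(seq)[::-1], k)


def encode_matrix_2d(seq: SeqLike, k: int) -> np.ndarray:
    """The k-mer code sequence laid out row-major in a near-square grid.

    Codes are 1-based (kmer_index + 1) so that 0 is reserved for the
    trailing padding cells; the side is ceil(sqrt(#tokens)), which is 7
    for all of k = 1, 2, 3 on 41-mers.
    """
    codes = _codes(seq, k) + 1
    side = math.isqrt(len(codes))
    if side * side < len(codes):
        side += 1
    grid = np.zeros(side * side, dtype=np.int64)
    grid[: len(codes)] = codes
    return grid.reshape(side, side)
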