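"""Packed storage of binary features, one bit per sample per feature.

A :class:`BitMatrix` stores binary derived features ("bits") column-major in
64-bit machine words, least-significant-bit first: within each word, bit
position ``k`` holds the value for sample ``word_index * 64 + k``.  Padding
bits beyond ``n_samples`` in the last word of every column are zero, so a
plain popcount over a column's words equals the number of set samples.

The packed layout is what lets the forest afford ~10,000 binary features:
grouped sums over a bootstrap subset reduce to word gathers, shifts and
``np.bitwise_count``.
"""

from __future__ import annotations

import numpy as np

WORD_SIZE = 64

__all__ = ["WORD_SIZE", "BitMatrix", "pack", "unpack", "group_sums"]


class BitMatrix:
    """Immutable packed binary feature matrix.

    Parameters
    ----------
    words : ndarray of uint64, shape (n_bits, n_words)
        Column-major packed bits; row ``j`` holds all words of bit-feature
        ``j``.
    n_samples : int
        Number of valid samples per column (the rest of the last word is
        zero padding).
    """

    __slots__ = ("words", "n_samples", "n_bits", "n_words")

    def __init__(self, words: np.ndarray, n_samples: int):
        words = np.ascontiguousarray(words, dtype=np.uint64)
        if words.ndim != 2:
            raise ValueError("words must be a 2-D (n_bits, n_words) array")
        expected_words = max((int(n_samples) + WORD_SIZE - 1) // WORD_SIZE, 0)
        if words.shape[1] != expected_words and words.shape[0] > 0:
            raise ValueError(
                f"expected {expected_words} words per column for "
                f"{n_samples} samples, got {words.shape[1]}"
            )
        self.words = words
        self.n_samples = int(n_samples)
        self.n_bits = int(words.shape[0])
        self.n_words = int(words.shape[1]) if words.shape[0] > 0 else expected_words

    # ------------------------------------------------------------------
    def column_popcount(self, bit_index: int) -> int:
        """Number of set samples in one bit column (padding is zero)."""
        self._check_bit(bit_index)
        return int(np.bitwise_count(self.words[bit_index]).sum())

    def get_bits(self, bit_index: int, sample_indices: np.ndarray | None = None) -> np.ndarray:
        """Extract one column as a uint8 {0,1} vector, optionally at a subset.

        ``sample_indices`` may contain repeats (bootstrap multiplicity); the
        result then has one entry per requested index.
        """
        self._check_bit(bit_index)
        if sample_indices is None:
            return unpack(self)[:, bit_index]
        idx = np.asarray(sample_indices, dtype=np.intp)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_samples):
            raise IndexError("sample index out of range")
        w = self.words[bit_index, idx >> 6]
        return ((w >> (idx.astype(np.uint64) & np.uint64(63))) & np.uint64(1)).astype(np.uint8)

    def extract(self, bit_indices: np.ndarray, sample_indices: np.ndarray) -> np.ndarray:
        """Dense uint8 block of shape (len(sample_indices), len(bit_indices)).

        Used by the forest to materialise a tree's bootstrapped bits once;
        repeats in ``sample_indices`` are honoured.
        """
        bidx = np.asarray(bit_indices, dtype=np.intp)
        sidx = np.asarray(sample_indices, dtype=np.intp)
        if bidx.size and (bidx.min() < 0 or bidx.max() >= self.n_bits):
            raise IndexError("bit index out of range")
        if sidx.size and (sidx.min() < 0 or sidx.max() >= self.n_samples):
            raise IndexError("sample index out of range")
        w = self.words[np.ix_(bidx, sidx >> 6)]  # (n_bits_sel, n_sel)
        shifts = sidx.astype(np.uint64) & np.uint64(63)
        bits = ((w >> shifts[None, :]) & np.uint64(1)).astype(np.uint8)
        return bits.T

    def _check_bit(self, bit_index: int) -> None:
        if not 0 <= bit_index < self.n_bits:
            raise IndexError(f"bit index {bit_index} out of range [0, {self.n_bits})")

    def __repr__(self) -> str:  # pragma: no cover
        return f"BitMatrix(n_samples={self.n_samples}, n_bits={self.n_bits})"


def pack(bit_columns, n_samples: int | None = None) -> BitMatrix:
    """Pack binary columns into a :class:`BitMatrix`.

    Parameters
    ----------
    bit_columns : sequence of 1-D {0,1} vectors, or 2-D array (n_samples, n_bits)
        All columns must share one length.
    n_samples : int, optional
        Required when ``bit_columns`` is empty (the sample count cannot be
        inferred from zero columns).
    """
    if isinstance(bit_columns, np.ndarray) and bit_columns.ndim == 2:
        cols = [bit_columns[:, j] for j in range(bit_columns.shape[1])]
    else:
        cols = list(bit_columns)
    if not cols:
        if n_samples is None:
            raise ValueError("n_samples is required when packing zero columns")
        n_words = (int(n_samples) + WORD_SIZE - 1) // WORD_SIZE
        return BitMatrix(np.zeros((0, n_words), dtype=np.uint64), n_samples)

    lengths = {len(c) for c in cols}
    if len(lengths) != 1:
        raise ValueError(f"ragged bit columns: lengths {sorted(lengths)}")
    n = lengths.pop()
    if n_samples is not None and n_samples != n:
        raise ValueError(f"declared n_samples={n_samples} but columns have length {n}")

    dense = np.asarray(cols)
    if not np.isin(dense, (0, 1)).all():
        raise ValueError("bit columns must contain only 0 and 1")
    dense = dense.astype(np.uint8)  # (n_bits, n_samples)

    # LSB-first within bytes, then little-endian bytes within each word.
    packed = np.packbits(dense, axis=1, bitorder="little")  # (n_bits, ceil(n/8))
    n_words = (n + WORD_SIZE - 1) // WORD_SIZE
    padded = np.zeros((dense.shape[0], n_words * 8), dtype=np.uint8)
    padded[:, : packed.shape[1]] = packed
    words = padded.view("<u8").astype(np.uint64)
    return BitMatrix(words, n)


def unpack(matrix: BitMatrix) -> np.ndarray:
    """Inverse of :func:`pack`: dense uint8 array (n_samples, n_bits)."""
    if matrix.n_bits == 0:
        return np.zeros((matrix.n_samples, 0), dtype=np.uint8)
    as_bytes = matrix.words.astype("<u8").view(np.uint8)  # (n_bits, n_words*8)
    bits = np.unpackbits(as_bytes, axis=1, bitorder="little")[:, : matrix.n_samples]
    return np.ascontiguousarray(bits.T)


def group_sums(
    matrix: BitMatrix,
    bit_index: int,
    values: np.ndarray,
    subset: np.ndarray,
) -> tuple[int, float, int, float]:
    """Counts and value sums of a subset split by one stored bit.

    ``subset`` is an index multiset (bootstrap repeats allowed).  Returns
    ``(n0, sum0, n1, sum1)`` where group membership of each subset entry is
    decided by its stored bit; ``n0 + n1 == len(subset)`` and
    ``sum0 + sum1 == values[subset].sum()``.
    """
    values = np.asarray(values, dtype=np.float64)
    subset = np.asarray(subset, dtype=np.intp)
    bits = matrix.get_bits(bit_index, subset)
    vals = values[subset]
    n1 = int(bits.sum())
    sum1 = float(vals @ bits)
    return len(subset) - n1, float(vals.sum()) - sum1, n1, sum1
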