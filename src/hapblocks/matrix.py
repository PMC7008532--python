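"""Haplotype matrix container and column-stream access.

A haplotype matrix has k rows (one per haplotype) and n columns (one per
variant site), with entries drawn from a small ordered alphabet of
non-negative integers -- {0, 1} for biallelic SNP data, where 0 is the
reference/ancestral allele and 1 the alternate/derived allele.

Indexing convention: arrays are stored 0-based internally; all *reported*
coordinates (block columns i, j and row indices in K) are 1-based inclusive.
The conversion happens exactly once, at the block-construction boundary in
:mod:`hapblocks.blocks`.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = ["HaplotypeMatrix", "ColumnStream"]


class HaplotypeMatrix:
    """A k x n matrix of haplotype symbols over a constant-size alphabet.

    Parameters
    ----------
    data:
        Array-like of shape (k, n) with small non-negative integer entries.
    alphabet:
        Ordered collection of admissible symbols. Defaults to the sorted set
        of symbols present in ``data`` (and ``(0, 1)`` for an empty matrix).
    row_ids, site_ids:
        Optional human-readable labels; defaults are generated.
    meta:
        Free-form provenance dictionary (e.g. generator seed).
    """

    def __init__(
        self,
        data,
        alphabet: Optional[Sequence[int]] = None,
        row_ids: Optional[Sequence[str]] = None,
        site_ids: Optional[Sequence[str]] = None,
        meta: Optional[dict] = None,
    ):
        arr = np.asarray(data, dtype=np.int16)
        if arr.ndim != 2:
            raise ValueError(f"haplotype matrix must be 2-dimensional, got shape {arr.shape}")
        self._data = arr
        if alphabet is None:
            if arr.size:
                alphabet = tuple(int(s) for s in np.unique(arr))
            else:
                alphabet = (0, 1)
        self.alphabet: tuple[int, ...] = tuple(sorted(int(s) for s in alphabet))
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("alphabet contains duplicate symbols")
        if arr.size and not set(np.unique(arr).tolist()) <= set(self.alphabet):
            bad = sorted(set(np.unique(arr).tolist()) - set(self.alphabet))
            raise ValueError(f"matrix contains symbols outside the alphabet: {bad}")
        k, n = arr.shape
        self.row_ids: list[str] = (
            list(row_ids) if row_ids is not None else [f"row{r}" for r in range(1, k + 1)]
        )
        if len(self.row_ids) != k:
            raise ValueError(f"expected {k} row_ids, got {len(self.row_ids)}")
        self.site_ids: Optional[list[str]] = list(site_ids) if site_ids is not None else None
        if self.site_ids is not None and len(self.site_ids) != n:
            raise ValueError(f"expected {n} site_ids, got {len(self.site_ids)}")
        self.meta: dict = dict(meta) if meta else {}

    # -- basic accessors -------------------------------------------------

    @property
    def k(self) -> int:
        return self._data.shape[0]

    @property
    def n(self) -> int:
        return self._data.shape[1]

    @property
    def data(self) -> np.ndarray:
        """The underlying (k, n) array; treat as read-only."""
        return self._data

    def values(self, row: int, col: int) -> int:
        """Symbol of 1-based ``row`` at 1-based ``col``."""
        if not (1 <= row <= self.k and 1 <= col <= self.n):
            raise IndexError(f"(row, col) = ({row}, {col}) outside 1-based bounds ({self.k}, {self.n})")
        return int(self._data[row - 1, col - 1])

    def column(self, col: int) -> np.ndarray:
        """1-based column ``col`` as a length-k vector in original row order."""
        if not (1 <= col <= self.n):
            raise IndexError(f"column {col} outside 1-based bounds [1, {self.n}]")
        return self._data[:, col - 1]

    def row_string(self, row: int) -> str:
        """1-based row as a digit string (convenience for tests/fixtures)."""
        return "".join(str(int(s)) for s in self._data[row - 1])

    def stream(self) -> "ColumnStream":
        """Column-stream view: yields the n columns left to right."""
        return ColumnStream(
            self.k,
            iter(self._data.T),
            n=self.n,
            alphabet=self.alphabet,
            row_ids=self.row_ids,
        )

    # -- equality on the abstract object ---------------------------------

    def __eq__(self, other) -> bool:
        # labels and metadata are carrier information, not part of the
        # abstract matrix; round-trips through plain-text dialects compare equal
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (
            self._data.shape == other._data.shape
            and bool(np.array_equal(self._data, other._data))
            and self.alphabet == other.alphabet
        )

    def __hash__(self):
        return hash((self._data.shape, self._data.tobytes(), self.alphabet))

    def __repr__(self) -> str:
        return f"HaplotypeMatrix(k={self.k}, n={self.n}, alphabet={self.alphabet})"

    @classmethod
    def from_strings(cls, rows: Iterable[str], **kwargs) -> "HaplotypeMatrix":
        """Build from digit strings, e.g. ``["010", "011", "110"]``."""
        parsed = [[int(c) for c in row] for row in rows]
        return cls(np.asarray(parsed, dtype=np.int16).reshape(len(parsed), -1), **kwargs)


class ColumnStream:
    """Iterator over the columns of a haplotype matrix, in column order.

    Supports the streaming model in which only O(k) working state is held:
    consumers see one length-k symbol vector at a time. ``n`` may be unknown
    upfront (e.g. when streaming a VCF).
    """

    def __init__(
        self,
        k: int,
        columns: Iterable[np.ndarray],
        n: Optional[int] = None,
        alphabet: Optional[Sequence[int]] = None,
        row_ids: Optional[Sequence[str]] = None,
    ):
        if k < 0:
            raise ValueError("k must be non-negative")
        self.k = k
        self.n = n
        self.alphabet = tuple(alphabet) if alphabet is not None else None
        self.row_ids = list(row_ids) if row_ids is not None else None
        self._columns = iter(columns)

    def __iter__(self) -> Iterator[np.ndarray]:
        for col in self._columns:
            vec = np.asarray(col)
            if vec.shape != (self.k,):
                raise ValueError(f"column has length {vec.shape}, expected ({self.k},)")
            yield vec
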