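"""Positional Burrows-Wheeler Transform maintained column by column.

After processing l columns the state holds, for the k row prefixes of
length l:

* ``a`` -- the colexicographic order: a permutation of {1..k} such that the
  prefixes S[a[1]][1,l] <= ... <= S[a[k]][1,l] when compared right-to-left;
* ``d`` -- the divergence array: d[1] = l + 1 and, for r > 1,
  d[r] = 1 + max{ j in [1,l] : S[a[r]][j] != S[a[r-1]][j] }, with the max
  over an empty set taken as 0, so two identical prefixes give d[r] = 1.

The empty-set convention lifts the usual all-rows-distinct assumption:
duplicate rows are fully supported and surface as divergence value 1.

Each column is absorbed in O(k * |alphabet|) time by a stable bucket pass
that generalises the classical binary two-bucket update to any constant-size
alphabet; for a binary alphabet it reduces exactly to that update.

Storage note: ``a`` and ``d`` are numpy arrays whose *position* r of the
definition is index r-1, while row values inside ``a`` are 1-based; this
keeps frozen test values directly comparable with the definitions above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["PBWTState", "initial_state", "extend", "invert"]


@dataclass(frozen=True)
class PBWTState:
    """pBWT arrays for one column; immutable, so the previous column's state
    stays readable while the next one is built (two-column window)."""

    l: int
    a: np.ndarray  # positions 0-based, values 1-based rows
    d: np.ndarray  # divergence values in [1, l+1]
    alphabet: tuple[int, ...]

    @property
    def k(self) -> int:
        return len(self.a)

    @property
    def a_inv(self) -> np.ndarray:
        """Inverse permutation: a_inv[a[r]] == r (both 1-based)."""
        return invert(self.a)

    def sorted_prefix_rows(self) -> list[int]:
        """Rows in colexicographic prefix order (1-based)."""
        return [int(r) for r in self.a]


def initial_state(k: int, alphabet: Sequence[int] = (0, 1)) -> PBWTState:
    """State before any column (l = 0): identity order, all divergences 1.

    All length-0 prefixes are identical, so the empty-max convention gives
    d[r] = 1 everywhere, which also equals l + 1 at position 1.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    return PBWTState(
        l=0,
        a=np.arange(1, k + 1, dtype=np.int64),
        d=np.ones(k, dtype=np.int64),
        alphabet=tuple(sorted(int(s) for s in alphabet)),
    )


def extend(state: PBWTState, column) -> PBWTState:
    """Absorb the next column, producing the state for l + 1.

    Stable bucket pass: one bucket per alphabet symbol, plus a per-symbol
    running maximum m_s initialised to l + 2 (the d[1] value of the new
    column). Scanning rows in current a-order, every m_s first absorbs the
    row's divergence; the row then lands in the bucket of its symbol in the
    new column, taking that bucket's running maximum as its new divergence,
    which resets to 0. Concatenating buckets in alphabet order yields the
    new a and d. The first row of each non-initial bucket keeps m = l + 2:
    it differs from its sorted predecessor at the new column itself.
    """
    col = np.asarray(column)
    k = state.k
    if col.shape != (k,):
        raise ValueError(f"column has shape {col.shape}, expected ({k},)")
    alphabet = state.alphabet
    sym_pos = {s: t for t, s in enumerate(alphabet)}
    nsym = len(alphabet)

    m = [state.l + 2] * nsym
    bucket_rows: list[list[int]] = [[] for _ in range(nsym)]
    bucket_div: list[list[int]] = [[] for _ in range(nsym)]
    a = state.a
    d = state.d
    for r in range(k):
        row = int(a[r])
        dr = int(d[r])
        for t in range(nsym):
            if m[t] < dr:
                m[t] = dr
        sym = int(col[row - 1])
        t = sym_pos.get(sym)
        if t is None:
            raise ValueError(f"symbol {sym} at row {row} outside alphabet {alphabet}")
        bucket_rows[t].append(row)
        bucket_div[t].append(m[t])
        m[t] = 0

    new_a = np.fromiter(
        (row for bucket in bucket_rows for row in bucket), dtype=np.int64, count=k
    )
    new_d = np.fromiter(
        (dv for bucket in bucket_div for dv in bucket), dtype=np.int64, count=k
    )
    return PBWTState(l=state.l + 1, a=new_a, d=new_d, alphabet=alphabet)


def invert(a) -> np.ndarray:
    """Inverse of a permutation of {1..k} (1-based values, 0-based storage)."""
    arr = np.asarray(a, dtype=np.int64)
    k = len(arr)
    if k == 0:
        return arr.copy()
    if sorted(arr.tolist()) != list(range(1, k + 1)):
        raise ValueError("input is not a permutation of {1..k}")
    inv = np.empty(k, dtype=np.int64)
    inv[arr - 1] = np.arange(1, k + 1, dtype=np.int64)
    return inv
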