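"""Maximal perfect haplotype blocks from the streamed pBWT.

A maximal perfect haplotype block is a triple (K, i, j), |K| >= 2, such
that all rows in K agree on columns [i, j] (equality) and the block can be
extended neither left (i = 1 or some pair in K disagrees at i-1), nor
right (j = n or some pair disagrees at j+1), nor by adding rows
(row-maximality). Its size is (j - i + 1) * |K|.

Per column j, candidates are read off the divergence array: a colex range
[x, y] with d_j[r] <= i on (x, y], some d_j[r] = i, and strictly larger
divergence just outside the range is an *available block* (i, j; x, y) --
it satisfies equality, left- and row-maximality. Available blocks are
exactly the LCP intervals of LCP_j[r] = j - d_j[r] + 1 with positive value,
enumerated in O(k) by a stack pass. Right-maximality is then a single
lookup in a prefix-sum index over the next column (or automatic at j = n).

Total cost is O(nk) time and O(k) working memory (compact ranges); row
sets are expanded from the live a_j before it is replaced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

import numpy as np

from ._intervals import lcp_intervals
from .matrix import ColumnStream, HaplotypeMatrix
from .pbwt import PBWTState, extend, initial_state

__all__ = [
    "AvailableBlock",
    "PerfectBlock",
    "RightMaxIndex",
    "lcp_from_divergence",
    "enumerate_available_blocks",
    "build_rightmax_index",
    "is_right_maximal",
    "find_blocks",
]


@dataclass(frozen=True)
class AvailableBlock:
    """Candidate block (i, j; x, y): a colex range satisfying equality,
    left-maximality and row-maximality at column j. 1-based throughout."""

    i: int
    j: int
    x: int
    y: int

    @property
    def n_rows(self) -> int:
        return self.y - self.x + 1

    @property
    def width(self) -> int:
        return self.j - self.i + 1


@dataclass(frozen=True)
class PerfectBlock:
    """A maximal perfect haplotype block (K, i, j); columns 1-based.

    ``rows`` is the 1-based row set K, or None in compact reporting, where
    the block is identified by its colex range [x, y] at column j instead.
    The colex range is carrier information and excluded from equality.
    """

    rows: Optional[frozenset[int]]
    i: int
    j: int
    x: Optional[int] = field(default=None, compare=False)
    y: Optional[int] = field(default=None, compare=False)

    @property
    def n_rows(self) -> int:
        if self.rows is not None:
            return len(self.rows)
        return self.y - self.x + 1

    @property
    def width(self) -> int:
        return self.j - self.i + 1

    @property
    def size(self) -> int:
        return self.width * self.n_rows

    def __repr__(self) -> str:
        K = "{" + ",".join(map(str, sorted(self.rows))) + "}" if self.rows is not None else f"[x={self.x},y={self.y}]"
        return f"PerfectBlock(K={K}, i={self.i}, j={self.j}, size={self.size})"


@dataclass(frozen=True)
class RightMaxIndex:
    """Prefix sums of the bit vector V_j over the colex order at column j:
    V_j[1] = 1 and V_j[r] = 1 iff rows a_j[r] and a_j[r-1] disagree at
    column j+1. "Some 1 in V_j[x+1, y]" is then an O(1) subtraction."""

    j: int
    prefix_sums: np.ndarray  # position r (1-based) at index r-1

    def any_change_in(self, x: int, y: int) -> bool:
        """True iff V_j[x+1, y] contains a 1-bit (x < y, 1-based)."""
        return int(self.prefix_sums[y - 1] - self.prefix_sums[x - 1]) > 0


def lcp_from_divergence(d, l: int) -> np.ndarray:
    """LCP_l[r] = l - d_l[r] + 1: longest common colex suffix lengths of
    adjacent sorted prefixes. LCP[1] is always 0 since d[1] = l + 1."""
    return l - np.asarray(d, dtype=np.int64) + 1


def enumerate_available_blocks(state: PBWTState) -> list[AvailableBlock]:
    """All available blocks ending at column j = state.l, each once.

    They are the LCP intervals of positive value: for an interval (v, x, y),
    all rows in the range share their last v columns (equality, with
    i = j - v + 1), the minimum being attained means some d_j[r] = i
    (left-maximality), and the interval boundaries give row-maximality.
    At most k - 1 intervals exist (branching trie nodes); O(k) time.
    """
    j = state.l
    if state.k < 2 or j < 1:
        return []
    lcp = lcp_from_divergence(state.d, j)
    out = []
    for value, x, y in lcp_intervals(lcp):
        if value >= 1 and y > x:
            out.append(AvailableBlock(i=j - value + 1, j=j, x=x, y=y))
    return out


def build_rightmax_index(state: PBWTState, next_column) -> RightMaxIndex:
    """Index for right-maximality tests at column j = state.l, built from
    column j+1 read in the current colex order a_j."""
    col = np.asarray(next_column)
    if col.shape != (state.k,):
        raise ValueError(f"next column has shape {col.shape}, expected ({state.k},)")
    in_a_order = col[state.a - 1]
    v = np.empty(state.k, dtype=np.int64)
    v[0] = 1
    v[1:] = in_a_order[1:] != in_a_order[:-1]
    return RightMaxIndex(j=state.l, prefix_sums=np.cumsum(v))


def is_right_maximal(
    block: AvailableBlock, index: Optional[RightMaxIndex], n: int
) -> bool:
    """Right-maximality test: automatic at j = n, else some pair of rows in
    the colex range [x, y] must disagree at column j + 1, i.e. V_j[x+1, y]
    contains a 1-bit."""
    if block.j == n:
        return True
    if index is None:
        raise ValueError(f"right-maximality at column {block.j} < n={n} needs the next-column index")
    if index.j != block.j:
        raise ValueError(f"index built for column {index.j}, block ends at {block.j}")
    return index.any_change_in(block.x, block.y)


def _column_blocks(
    state: PBWTState,
    index: Optional[RightMaxIndex],
    n: Optional[int],
    min_size: int,
    expand_rows: bool,
) -> Iterator[PerfectBlock]:
    """Blocks ending at the current column, x-ascending. ``index`` is None
    only on the final column (j = n branch)."""
    avail = enumerate_available_blocks(state)
    avail.sort(key=lambda b: b.x)
    for blk in avail:
        if index is not None and not index.any_change_in(blk.x, blk.y):
            continue
        if blk.width * blk.n_rows < min_size:
            continue
        rows = (
            frozenset(int(r) for r in state.a[blk.x - 1 : blk.y])
            if expand_rows
            else None
        )
        yield PerfectBlock(rows=rows, i=blk.i, j=blk.j, x=blk.x, y=blk.y)


def find_blocks(
    source: Union[HaplotypeMatrix, ColumnStream],
    min_size: int = 1,
    expand_rows: bool = True,
) -> Iterator[PerfectBlock]:
    """Stream all maximal perfect haplotype blocks of size >= ``min_size``.

    Blocks are emitted grouped by end column j ascending and, within a
    column, by colex start x ascending -- a deterministic order. With
    ``expand_rows`` each block carries its explicit row set K (expanded
    from the live a_j); otherwise only the colex range (x, y) is kept and
    working memory stays O(k).
    """
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    stream = source.stream() if isinstance(source, HaplotypeMatrix) else source
    if stream.k < 2:
        raise ValueError(f"block finding requires k >= 2 haplotypes, got k={stream.k}")
    alphabet = stream.alphabet if stream.alphabet is not None else (0, 1)
    state = initial_state(stream.k, alphabet)
    for col in stream:
        if state.l >= 1:
            index = build_rightmax_index(state, col)
            yield from _column_blocks(state, index, None, min_size, expand_rows)
        state = extend(state, col)
    if state.l >= 1:
        # final column: right-maximality holds trivially at j = n
        yield from _column_blocks(state, None, state.l, min_size, expand_rows)
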