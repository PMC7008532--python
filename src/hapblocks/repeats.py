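"""Block finding by maximal-repeat detection on a decorated concatenation.

Independent second route, used to cross-validate the pBWT path. Each row
s_i is interleaved with per-column index characters,

    s_i+ = a_0 s_i[1] a_1 s_i[2] a_2 ... s_i[n] a_n,

the same a_p symbols across rows, and the decorated rows are concatenated
with k pairwise-distinct separators. The index characters force every
occurrence of a repeat to sit at the same matrix columns, and the unique
separators prevent repeats from spanning rows. A maximal repeat of the
form a_p r_1 a_{p+1} ... r_l a_{p+l} with l >= 1 then corresponds
one-to-one to a maximal perfect haplotype block (K, p+1, p+l), where K is
read off the occurrence positions and |K| equals the occurrence count.

Maximal repeats are extracted from the suffix array + LCP array: every LCP
interval of positive value is right-maximal by construction and is a
maximal repeat iff the characters preceding its suffixes are not all equal.

Integer encoding (fixed layout): matrix symbols map to [0, |S|) by rank in
the alphabet, index character a_p to |S| + p, separator of row r (1-based)
to |S| + n + 1 + (r - 1). This route keeps the whole O(kn)-integer string
in memory; it is a correctness cross-check, not the streaming path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._intervals import lcp_intervals
from .blocks import PerfectBlock
from .matrix import HaplotypeMatrix

__all__ = [
    "DecoratedString",
    "MaximalRepeat",
    "decorate",
    "suffix_array",
    "lcp_array",
    "maximal_repeats",
    "blocks_from_repeats",
]


@dataclass(frozen=True)
class DecoratedString:
    """The decorated concatenation with its encoding map and back-mapping."""

    seq: np.ndarray
    k: int
    n: int
    alphabet: tuple[int, ...]

    @property
    def index_base(self) -> int:
        """Encoded value of index character a_0."""
        return len(self.alphabet)

    @property
    def separator_base(self) -> int:
        """Encoded value of the first row separator."""
        return len(self.alphabet) + self.n + 1

    @property
    def row_span(self) -> int:
        """Encoded length of one decorated row incl. its separator."""
        return 2 * self.n + 2

    def is_index_char(self, symbol: int) -> bool:
        return self.index_base <= symbol < self.separator_base

    def back_map(self, pos: int) -> tuple[str, int, int]:
        """Classify position ``pos``: ("site", row, column) for a matrix
        symbol, ("index", row, p) for index character a_p, or
        ("separator", row, 0). Row and column are 1-based."""
        if not 0 <= pos < len(self.seq):
            raise IndexError(f"position {pos} outside decorated string of length {len(self.seq)}")
        row = pos // self.row_span + 1
        within = pos % self.row_span
        if within == self.row_span - 1:
            return ("separator", row, 0)
        if within % 2 == 0:
            return ("index", row, within // 2)
        return ("site", row, (within + 1) // 2)


@dataclass(frozen=True)
class MaximalRepeat:
    """A substring occurring >= 2 times, extendable in neither direction."""

    text: tuple[int, ...]
    occ: tuple[int, ...]  # sorted start positions

    @property
    def length(self) -> int:
        return len(self.text)


def decorate(matrix: HaplotypeMatrix) -> DecoratedString:
    """Build the decorated concatenation of all rows of ``matrix``."""
    k, n = matrix.k, matrix.n
    if k < 1 or n < 1:
        raise ValueError(f"cannot decorate an empty matrix (k={k}, n={n})")
    alphabet = matrix.alphabet
    rank = {s: t for t, s in enumerate(alphabet)}
    nsig = len(alphabet)
    span = 2 * n + 2
    seq = np.empty(k * span, dtype=np.int64)
    for r in range(k):
        base = r * span
        seq[base : base + 2 * n + 1 : 2] = nsig + np.arange(n + 1)  # a_0 .. a_n
        seq[base + 1 : base + 2 * n : 2] = [rank[int(s)] for s in matrix.data[r]]
        seq[base + span - 1] = nsig + n + 1 + r  # unique separator
    return DecoratedString(seq=seq, k=k, n=n, alphabet=alphabet)


def suffix_array(s) -> np.ndarray:
    """Suffix array of an integer sequence by prefix doubling (O(m log m))."""
    arr = np.asarray(s, dtype=np.int64)
    m = len(arr)
    if m == 0:
        return np.empty(0, dtype=np.int64)
    rank = np.unique(arr, return_inverse=True)[1].astype(np.int64)
    sa = np.argsort(rank, kind="stable")
    h = 1
    while rank[sa[-1]] < m - 1 and h < m:
        key2 = np.full(m, -1, dtype=np.int64)
        key2[: m - h] = rank[h:]
        sa = np.lexsort((key2, rank))
        r1, r2 = rank[sa], key2[sa]
        bump = np.empty(m, dtype=np.int64)
        bump[0] = 0
        bump[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        rank = np.empty(m, dtype=np.int64)
        rank[sa] = np.cumsum(bump)
        h *= 2
    return sa


def lcp_array(s, sa: np.ndarray) -> np.ndarray:
    """Kasai LCP array: lcp[r] = lcp(suffix sa[r-1], suffix sa[r]), lcp[0] = 0."""
    arr = np.asarray(s, dtype=np.int64)
    m = len(arr)
    inv = np.empty(m, dtype=np.int64)
    inv[sa] = np.arange(m)
    lcp = np.zeros(m, dtype=np.int64)
    h = 0
    for pos in range(m):
        r = inv[pos]
        if r > 0:
            prev = sa[r - 1]
            while pos + h < m and prev + h < m and arr[pos + h] == arr[prev + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


def maximal_repeats(s) -> list[MaximalRepeat]:
    """All maximal repeats of an integer sequence.

    Every LCP interval of value v >= 1 groups the occurrences of one
    right-maximal substring; it is a maximal repeat iff it is also
    left-diverse: the preceding characters of its suffixes are not all
    equal (a suffix starting at position 0 counts as unextendable).
    """
    arr = np.asarray(s, dtype=np.int64)
    m = len(arr)
    if m == 0:
        return []
    sa = suffix_array(arr)
    lcp = lcp_array(arr, sa)
    prev_char = np.where(sa > 0, arr[np.maximum(sa - 1, 0)], np.int64(-1))
    out = []
    for value, x, y in lcp_intervals(lcp):
        if value < 1 or y <= x:
            continue
        window = prev_char[x - 1 : y]
        if np.all(window == window[0]) and window[0] != -1:
            continue  # all occurrences extend left by the same character
        start = int(sa[x - 1])
        out.append(
            MaximalRepeat(
                text=tuple(int(c) for c in arr[start : start + value]),
                occ=tuple(sorted(int(p) for p in sa[x - 1 : y])),
            )
        )
    return out


def blocks_from_repeats(matrix: HaplotypeMatrix, min_size: int = 1) -> set[PerfectBlock]:
    """Maximal perfect haplotype blocks via the decorated-string reduction.

    Keeps maximal repeats that both start and end with an index character
    and span at least one matrix column (l >= 1); each maps to the block
    (K, p+1, p+l) with K recovered through the back-mapping.
    """
    if matrix.k < 2:
        raise ValueError(f"block finding requires k >= 2 haplotypes, got k={matrix.k}")
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    dec = decorate(matrix)
    out: set[PerfectBlock] = set()
    for rep in maximal_repeats(dec.seq):
        first, last = rep.text[0], rep.text[-1]
        if not (dec.is_index_char(first) and dec.is_index_char(last)):
            continue
        width = (rep.length - 1) // 2
        if width < 1:
            continue
        p = first - dec.index_base
        rows = []
        for pos in rep.occ:
            kind, row, slot = dec.back_map(pos)
            assert kind == "index" and slot == p, "occurrence not column-aligned"
            rows.append(row)
        K = frozenset(rows)
        assert len(K) == len(rep.occ), "repeat occurs twice in one row"
        if width * len(K) >= min_size:
            out.add(PerfectBlock(rows=K, i=p + 1, j=p + width))
    return out
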