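"""Brute-force reference enumeration of maximal perfect haplotype blocks.

Ground truth for testing: O(n^2) column pairs, each grouped in O(k * n).
For every (i, j) the rows are partitioned by their substring on [i, j];
using the *maximal* equality classes makes row-maximality structural, so
only left-maximality (i = 1 or the class disagrees somewhere at i-1) and
right-maximality (j = n or disagreement at j+1) remain to check.
"""

from __future__ import annotations

from .blocks import PerfectBlock
from .matrix import HaplotypeMatrix

__all__ = ["brute_force_blocks"]


def brute_force_blocks(matrix: HaplotypeMatrix, min_size: int = 1) -> set[PerfectBlock]:
    """All maximal perfect haplotype blocks of ``matrix`` with size >= min_size."""
    if matrix.k < 2:
        raise ValueError(f"block finding requires k >= 2 haplotypes, got k={matrix.k}")
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    data = matrix.data
    k, n = matrix.k, matrix.n
    out: set[PerfectBlock] = set()
    for i in range(1, n + 1):
        for j in range(i, n + 1):
            classes: dict[bytes, list[int]] = {}
            for r in range(k):
                classes.setdefault(data[r, i - 1 : j].tobytes(), []).append(r + 1)
            for members in classes.values():
                if len(members) < 2:
                    continue
                if i > 1:
                    left_col = {int(data[r - 1, i - 2]) for r in members}
                    if len(left_col) == 1:
                        continue  # extendable left
                if j < n:
                    right_col = {int(data[r - 1, j]) for r in members}
                    if len(right_col) == 1:
                        continue  # extendable right
                if (j - i + 1) * len(members) >= min_size:
                    out.add(PerfectBlock(rows=frozenset(members), i=i, j=j))
    return out
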