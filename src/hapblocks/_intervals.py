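"""Stack-based enumeration of LCP intervals.

An LCP interval of value v is a maximal range [x, y] (1-based, x < y)
such that LCP[r] >= v for all r in [x+1, y], min equals v, and the
boundary entries LCP[x] and LCP[y+1] (where they exist) are < v. These
intervals are in bijection with the branching internal nodes of the
corresponding (suffix or prefix) trie. Each interval is emitted exactly
once, at its rightmost end, in O(len(lcp)) total time.
"""

from __future__ import annotations

from typing import Iterator, Sequence, Tuple

__all__ = ["lcp_intervals"]


def lcp_intervals(lcp: Sequence[int]) -> Iterator[Tuple[int, int, int]]:
    """Yield (value, x, y) for every LCP interval of ``lcp``.

    ``lcp`` is 1-based in spirit: entry 0 compares nothing and must be 0.
    The degenerate root interval (value 0 spanning everything) is included;
    callers filter by value as needed.
    """
    k = len(lcp)
    if k == 0:
        return
    stack: list[tuple[int, int]] = [(0, 1)]  # (value, left boundary)
    for r in range(2, k + 1):
        cur = int(lcp[r - 1])
        # lcp[r] compares sorted entries r-1 and r, so a fresh interval
        # opened here reaches back to r-1
        left = r - 1
        while stack and stack[-1][0] > cur:
            value, lb = stack.pop()
            yield value, lb, r - 1
            left = lb
        if not stack or stack[-1][0] < cur:
            stack.append((cur, left))
    while stack:
        value, lb = stack.pop()
        yield value, lb, k
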