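import itertools

import numpy as np
import pytest

from hapblocks.matrix import HaplotypeMatrix


@pytest.fixture
def fixture_matrix() -> HaplotypeMatrix:
    """The worked 3x3 example: rows 010, 011, 110."""
    return HaplotypeMatrix.from_strings(["010", "011", "110"])


def block_key(blocks):
    """Canonical comparable form of a block collection: {(K, i, j)}."""
    return {(tuple(sorted(b.rows)), b.i, b.j) for b in blocks}


def exhaustive_binary_matrices(k: int, n: int):
    """All 2^(k*n) binary k x n matrices."""
    for bits in itertools.product((0, 1), repeat=k * n):
        yield HaplotypeMatrix(
            np.asarray(bits, dtype=np.int16).reshape(k, n), alphabet=(0, 1)
        )


def random_matrices(count: int, seed: int, k_max: int = 12, n_max: int = 40):
    """Seeded random matrices, alphabet sizes 2-4, duplicate rows encouraged."""
    rng = np.random.default_rng(seed)
    for _ in range(count):
        k = int(rng.integers(2, k_max + 1))
        n = int(rng.integers(1, n_max + 1))
        sigma = int(rng.integers(2, 5))
        data = rng.integers(0, sigma, size=(k, n), dtype=np.int16)
        if rng.random() < 0.3 and k >= 3:
            # force duplicate rows to exercise the empty-max convention
            data[int(rng.integers(1, k))] = data[0]
        yield HaplotypeMatrix(data, alphabet=tuple(range(sigma)))


def pbwt_oracle(data: np.ndarray, l: int):
    """Definition-based pBWT at prefix length l: direct colexicographic sort
    of the length-l prefixes (ties by original row order) and the mismatch
    formula for the divergence array, max over the empty set taken as 0."""
    k = data.shape[0]
    order = sorted(range(k), key=lambda r: (tuple(data[r, :l][::-1]), r))
    a = [r + 1 for r in order]
    d = [l + 1]
    for idx in range(1, k):
        p, q = data[order[idx], :l], data[order[idx - 1], :l]
        mismatches = [c + 1 for c in range(l) if p[c] != q[c]]
        d.append(1 + max(mismatches) if mismatches else 1)
    return a, d
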