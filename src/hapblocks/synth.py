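"""Synthetic haplotype matrices: uniform noise and founder-copy structure.

The uniform model draws i.i.d. symbols and produces essentially no large
shared blocks; the founder-copy model emulates the haplotype sharing that
selection scans exploit: a small number of founder haplotypes are drawn
uniformly and each output row copies one of them, switching founders with
probability rho per site (a crude recombination stand-in) and flipping the
copied symbol with probability mu per site (mutation/genotyping noise).
Low mu and rho give long runs of identical rows and hence large,
size-filterable blocks. This is deliberately not a coalescent simulator.

Defaults model a small resequencing panel: k=50 haplotypes, n=200 biallelic
sites, f=5 founders, mu=rho=0.01 per site.

All randomness flows through one seeded numpy generator; the seed is
recorded in the matrix metadata for replay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .matrix import HaplotypeMatrix

__all__ = ["SynthConfig", "random_matrix", "founder_copy_matrix", "generate"]


@dataclass
class SynthConfig:
    """Parameters of the synthetic generators.

    mu and rho are per-site probabilities in [0, 1]; f is the number of
    founder haplotypes (founder-copy model only).
    """

    k: int = 50
    n: int = 200
    alphabet_size: int = 2
    seed: Optional[int] = None
    model: str = "uniform"
    f: int = 5
    mu: float = 0.01
    rho: float = 0.01

    def __post_init__(self):
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.alphabet_size < 2:
            raise ValueError(f"alphabet size must be >= 2, got {self.alphabet_size}")
        if self.model not in ("uniform", "founder-copy"):
            raise ValueError(f"unknown model {self.model!r}")
        if not (0.0 <= self.mu <= 1.0 and 0.0 <= self.rho <= 1.0):
            raise ValueError(f"mu and rho must lie in [0, 1], got mu={self.mu}, rho={self.rho}")
        if self.f < 1:
            raise ValueError(f"f must be >= 1, got {self.f}")


def random_matrix(config: SynthConfig) -> HaplotypeMatrix:
    """Uniform i.i.d. matrix; identical seeds give identical matrices."""
    if config.model != "uniform":
        raise ValueError(f"random_matrix requires model='uniform', got {config.model!r}")
    rng = np.random.default_rng(config.seed)
    data = rng.integers(0, config.alphabet_size, size=(config.k, config.n), dtype=np.int16)
    return HaplotypeMatrix(
        data,
        alphabet=tuple(range(config.alphabet_size)),
        meta={"model": "uniform", "seed": config.seed},
    )


def founder_copy_matrix(config: SynthConfig) -> HaplotypeMatrix:
    """Founder-copy matrix with per-site founder switching and mutation."""
    if config.model != "founder-copy":
        raise ValueError(f"founder_copy_matrix requires model='founder-copy', got {config.model!r}")
    if config.f > config.k:
        warnings.warn(
            f"more founders (f={config.f}) than haplotypes (k={config.k}); "
            "some founders will be unused",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    k, n, f, sigma = config.k, config.n, config.f, config.alphabet_size
    founders = rng.integers(0, sigma, size=(f, n), dtype=np.int16)

    # founder index per (row, site): start uniform, redraw on each switch
    assignment = np.empty((k, n), dtype=np.int64)
    assignment[:, 0] = rng.integers(0, f, size=k)
    switches = rng.random(size=(k, n)) < config.rho
    redraws = rng.integers(0, f, size=(k, n))
    for c in range(1, n):
        assignment[:, c] = np.where(switches[:, c], redraws[:, c], assignment[:, c - 1])

    data = founders[assignment, np.arange(n)]

    mutate = rng.random(size=(k, n)) < config.mu
    if sigma == 2:
        data = np.where(mutate, 1 - data, data)
    else:
        # replace with a uniformly chosen *different* symbol
        shift = rng.integers(1, sigma, size=(k, n))
        data = np.where(mutate, (data + shift) % sigma, data)

    return HaplotypeMatrix(
        data.astype(np.int16),
        alphabet=tuple(range(sigma)),
        meta={
            "model": "founder-copy",
            "seed": config.seed,
            "f": f,
            "mu": config.mu,
            "rho": config.rho,
            "founder_assignment": assignment,
        },
    )


def generate(config: SynthConfig) -> HaplotypeMatrix:
    """Dispatch on ``config.model``."""
    if config.model == "uniform":
        return random_matrix(config)
    return founder_copy_matrix(config)
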