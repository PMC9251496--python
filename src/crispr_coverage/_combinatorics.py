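"""Ranking of k-subsets of genes into a dense [0, C(x,k)) index.

Coverage bookkeeping stores, per k-combination of genes, the first plant
in which it appeared. The combinatorial number system (colexicographic
ranking) maps a sorted k-subset ``c_0 < c_1 < ... < c_{k-1}`` to

    rank = C(c_0, 1) + C(c_1, 2) + ... + C(c_{k-1}, k)

which is a bijection onto ``0 .. C(x,k) - 1``.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

__all__ = ["binom_table", "colex_rank", "colex_unrank", "all_combinations"]


def binom_table(x: int, k: int) -> np.ndarray:
    """Table ``T[n, j] = C(n, j)`` for ``0 <= n <= x``, ``0 <= j <= k``."""
    table = np.zeros((x + 1, k + 1), dtype=np.int64)
    for n in range(x + 1):
        for j in range(min(n, k) + 1):
            table[n, j] = comb(n, j)
    return table


def colex_rank(subsets: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Colex ranks of row-wise *sorted* k-subsets (shape (n, k))."""
    subsets = np.atleast_2d(subsets)
    k = subsets.shape[1]
    rank = np.zeros(subsets.shape[0], dtype=np.int64)
    for j in range(k):
        rank += table[subsets[:, j], j + 1]
    return rank


def colex_unrank(rank: int, x: int, k: int) -> tuple[int, ...]:
    """Inverse of :func:`colex_rank` for a single rank."""
    out = []
    remaining = rank
    for j in range(k, 0, -1):
        # largest c with C(c, j) <= remaining
        c = j - 1
        while comb(c + 1, j) <= remaining:
            c += 1
        out.append(c)
        remaining -= comb(c, j)
    return tuple(reversed(out))


def all_combinations(x: int, k: int) -> np.ndarray:
    """All k-subsets of range(x) in colex rank order, shape (C(x,k), k)."""
    combos = np.array(
        sorted(itertools.combinations(range(x), k), key=lambda c: tuple(reversed(c))),
        dtype=np.int64,
    ).reshape(comb(x, k), k)
    return combos
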