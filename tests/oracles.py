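"""Independent brute-force oracles used by the tests.

Deliberately naive double/triple loops over plain Python structures, sharing
no code path with the package's vectorized implementations.
"""

from __future__ import annotations

import itertools
import math


def brute_gower(trait_columns: dict[str, list[float]]):
    """Pairwise mean range-normalized distance; returns nested lists."""
    names = list(trait_columns)
    n = len(trait_columns[names[0]])
    ranges = {k: max(v) - min(v) for k, v in trait_columns.items()}
    out = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            out[i][j] = sum(
                abs(trait_columns[k][i] - trait_columns[k][j]) / ranges[k] for k in names
            ) / len(names)
    return out


def brute_mpd(cover: list[float], dist, weighted: bool = False):
    present = [i for i, a in enumerate(cover) if a > 0]
    if len(present) < 2:
        return None
    if not weighted:
        pairs = list(itertools.combinations(present, 2))
        return sum(dist[i][j] for i, j in pairs) / len(pairs)
    total = sum(cover[i] for i in present)
    num = den = 0.0
    for i in present:
        for j in present:
            if i != j:
                w = (cover[i] / total) * (cover[j] / total)
                num += w * dist[i][j]
                den += w
    return num / den


def brute_cwm(cover: list[float], traits: list[float]):
    total = sum(cover)
    if total <= 0:
        return None
    return sum(a * t for a, t in zip(cover, traits)) / total


def brute_ses(obs: float, null_values: list[float]):
    m = sum(null_values) / len(null_values)
    var = sum((v - m) ** 2 for v in null_values) / (len(null_values) - 1)
    sd = math.sqrt(var)
    return None if sd == 0 else (obs - m) / sd


def presence_marginals(matrix) -> tuple[tuple, tuple]:
    rows = tuple(sum(1 for v in row if v > 0) for row in matrix)
    cols = tuple(sum(1 for row in matrix if row[c] > 0) for c in range(len(matrix[0])))
    return rows, cols
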