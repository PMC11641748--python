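"""Independent brute-force oracles used to verify the implementation.

These deliberately share no code with the package: alignment scores come
from a plain Gotoh dynamic program, Spearman's rho from an O(n^2) rank
computation with explicit moment sums, and the repeated-measures F from
the textbook paired-t formula.
"""

from __future__ import annotations

import math


def gotoh_score(a: str, b: str, match: float = 2.0, mismatch: float = -1.0,
                gap_open: float = -6.0, gap_extend: float = -1.0) -> float:
    """Optimal global affine-gap alignment score.

    A gap of length L costs ``gap_open + L * gap_extend`` (both negative).
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    # M: a[i] aligned to b[j]; X: gap in b (deletion); Y: gap in a (insertion)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]
    Y = [[neg] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + i * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + j * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open + gap_extend, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open + gap_extend, Y[i][j - 1] + gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


def brute_force_ranks(values) -> list[float]:
    """Average ranks computed by pairwise counting (no sorting library)."""
    ranks = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def spearman_brute(x, y) -> float:
    """Spearman's rho from explicit rank moments, O(n^2)."""
    rx, ry = brute_force_ranks(x), brute_force_ranks(y)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)


def paired_t(x, y) -> float:
    """Paired t statistic for two matched samples."""
    d = [b - a for a, b in zip(x, y)]
    n = len(d)
    mean = sum(d) / n
    var = sum((v - mean) ** 2 for v in d) / (n - 1)
    return mean / math.sqrt(var / n)


def hamming_occurrences(text: str, pattern: str, max_mismatches: int) -> list[int]:
    """All start positions where pattern matches text with <= k mismatches."""
    hits = []
    for i in range(len(text) - len(pattern) + 1):
        mm = sum(1 for a, b in zip(text[i : i + len(pattern)], pattern) if a != b)
        if mm <= max_mismatches:
            hits.append(i)
    return hits
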