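"""Expression-level vs editing-efficiency rank correlation.

Counts are normalised with median-of-ratios size factors and a log2(x+1)
transform (a stand-in for the regularised log: Spearman correlation
downstream only sees ranks, which any monotone normalisation preserves),
averaged over replicates, matched to per-gene narrow-window editing
efficiencies by gene id, and summarised by Spearman's rank correlation
with a t-approximation p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionTable:
    """Normalised expression per gene (log2 scale, replicate mean)."""

    normalized: pd.Series  # gene -> mean log2 normalised value
    size_factors: pd.Series  # replicate -> size factor
    log_counts: pd.DataFrame  # gene x replicate, log2 normalised


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError("rho outside [-1, 1]")
        if self.n < 5:
            raise ValueError("n must be at least 5")


def normalize_counts(counts: pd.DataFrame) -> ExpressionTable:
    """Median-of-ratios normalisation followed by log2(x + 1).

    Size factors are the per-replicate median ratio to the gene-wise
    geometric mean (computed over genes with all-positive counts) and are
    rescaled to median 1, so equal columns get factor 1 and a doubled
    column gets factor 2.
    """
    if counts.shape[1] < 2:
        raise ValueError("at least two replicate columns are required")
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every replicate; size factors undefined")
    log_geo = np.log(counts.loc[positive]).mean(axis=1)
    ratios = np.log(counts.loc[positive]).sub(log_geo, axis=0)
    size_factors = np.exp(ratios.median(axis=0))
    size_factors = size_factors / size_factors.median()
    log_counts = np.log2(counts.div(size_factors, axis=1) + 1.0)
    return ExpressionTable(
        normalized=log_counts.mean(axis=1),
        size_factors=size_factors,
        log_counts=log_counts,
    )


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    rho is the Pearson correlation of the rank vectors; the p-value uses
    the t approximation with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 5:
        raise ValueError("at least five observations are required")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero variance in ranks; correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-15:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=rho, p_value=p, n=n)


def spearman_permutation_p(x, y, n_permutations: int = 10000, seed: int = 0) -> float:
    """Seeded permutation p-value for small n, as an alternative to the t approximation."""
    rng = np.random.default_rng(seed)
    observed = abs(spearman(x, y).rho)
    y = np.asarray(y, dtype=float)
    hits = 0
    for _ in range(n_permutations):
        if abs(spearman(x, rng.permutation(y)).rho) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def correlate_expression_editing(
    expression: ExpressionTable, editing: pd.Series
) -> tuple[CorrelationResult, pd.DataFrame, list[str]]:
    """Match genes by id and correlate expression with editing efficiency.

    Returns the correlation, the matched-pairs table, and the ids present
    in only one of the inputs.
    """
    matched = expression.normalized.index.intersection(editing.index)
    unmatched = sorted(
        set(expression.normalized.index).symmetric_difference(editing.index)
    )
    if len(matched) < 5:
        raise ValueError(f"only {len(matched)} matched genes; at least 5 required")
    pairs = pd.DataFrame(
        {
            "expression": expression.normalized.loc[matched],
            "aee2": editing.loc[matched],
        }
    )
    result = spearman(pairs["expression"].values, pairs["aee2"].values)
    return result, pairs, unmatched
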