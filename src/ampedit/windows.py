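"""Narrow-vs-wide window contrast, threshold derivation and proportion stats.

Editing estimated in a 2-nt window hugging the cut site is compared with a
20-nt window; when genetic variation lurks in the flanks the wide window
inflates, so the paired difference in percentage points is the screening
statistic.  The discrepancy threshold is derived from the positive control
(the largest discrepancy observed there, rounded to whole percentage
points), and sgRNAs are split into concordant / discordant groups at that
threshold.  Proportions are arcsine-transformed before the variance and
repeated-measures tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .align import Scoring
from .quant import Amplicon, GuideSpec, align_readset, quantify


@dataclass(frozen=True)
class DualWindowResult:
    """AEE at the 2-nt and 20-nt windows for one sample."""

    aee2: float
    aee20: float

    def __post_init__(self) -> None:
        for v in (self.aee2, self.aee20):
            if not 0.0 <= v <= 1.0:
                raise ValueError("AEE values must lie in [0, 1]")
        if self.delta_pp < -1e-9:
            raise ValueError(
                "AEE(2) exceeds AEE(20); the windows are nested so this cannot happen"
            )

    @property
    def delta_pp(self) -> float:
        """Wide-minus-narrow AEE difference in percentage points."""
        return 100.0 * (self.aee20 - self.aee2)


@dataclass(frozen=True)
class ThresholdSpec:
    """Discrepancy threshold in percentage points."""

    value_pp: float
    provenance: str  # derived | fixed

    def __post_init__(self) -> None:
        if self.value_pp <= 0:
            raise ValueError("threshold must be positive")
        if self.provenance not in ("derived", "fixed"):
            raise ValueError("provenance must be 'derived' or 'fixed'")


@dataclass(frozen=True)
class GroupSummary:
    n_below: int
    n_above: int

    @property
    def total(self) -> int:
        return self.n_below + self.n_above

    @property
    def fraction_below(self) -> float | None:
        return self.n_below / self.total if self.total else None


def dual_window_aee(
    reads: Iterable,
    amplicon: Amplicon,
    guide: GuideSpec,
    scoring: Scoring | None = None,
    aligned=None,
) -> DualWindowResult:
    """Compute AEE at both windows on one shared alignment pass."""
    from .quant import _as_sequences

    if aligned is None:
        aligned = align_readset(_as_sequences(reads), amplicon.sequence, scoring)
    a2 = quantify((), amplicon, guide, 2, aligned=aligned)
    a20 = quantify((), amplicon, guide, 20, aligned=aligned)
    return DualWindowResult(aee2=a2.aee, aee20=a20.aee)


def _as_dual(result) -> DualWindowResult:
    if isinstance(result, DualWindowResult):
        return result
    aee2, aee20 = result
    return DualWindowResult(aee2=float(aee2), aee20=float(aee20))


def derive_threshold(control_results: Sequence) -> ThresholdSpec:
    """Threshold = largest control discrepancy, rounded to whole pp.

    Accepts DualWindowResults or plain ``(aee2, aee20)`` pairs, e.g. the
    positive-control window values of a run.  A degenerate (zero) maximum
    is an error: the threshold must be positive to be usable.
    """
    if not control_results:
        raise ValueError("at least one positive-control result is required")
    max_delta = max(_as_dual(r).delta_pp for r in control_results)
    value = math.floor(max_delta + 0.5)  # round half up to the nearest pp
    if value <= 0:
        raise ValueError("degenerate threshold: control windows are identical")
    return ThresholdSpec(value_pp=float(value), provenance="derived")


def group_sgrnas(
    results: Sequence, threshold: ThresholdSpec
) -> tuple[GroupSummary, list[str]]:
    """Partition sgRNAs at the threshold (boundary goes to the concordant group)."""
    labels = []
    for r in results:
        d = _as_dual(r).delta_pp
        labels.append("below" if d <= threshold.value_pp else "above")
    summary = GroupSummary(
        n_below=labels.count("below"), n_above=labels.count("above")
    )
    return summary, labels


def arcsine_transform(p):
    """Variance-stabilising arcsin(sqrt(p)) for proportions in [0, 1]."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def levene_test(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Mean-centred Levene test of homogeneity of variance."""
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    devs = [np.abs(a - a.mean()) for a in arrays]
    if all(np.allclose(d, 0) for d in devs):
        raise ValueError("zero within-group deviation everywhere; W is undefined")
    if np.concatenate(devs).std() == 0:
        # identical absolute deviations in every group: no variance signal
        return 0.0, 1.0
    w, p = stats.levene(*arrays, center="mean")
    return float(w), float(p)


def compare_window_distributions(
    narrow: Sequence[float], wide: Sequence[float]
) -> tuple[float, float]:
    """Two-level within-subject repeated-measures ANOVA.

    Each sgRNA is measured at both windows, so the within-subject ANOVA
    reduces to the square of the paired t statistic, with the p-value from
    F(1, n-1).  Inputs are expected on the arcsine scale already.
    """
    x = np.asarray(narrow, dtype=float)
    y = np.asarray(wide, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired vectors of equal length are required")
    n = x.size
    if n < 3:
        raise ValueError("at least three paired observations are required")
    d = y - x
    if np.allclose(d, d[0]) and np.isclose(d[0], 0.0):
        return 0.0, 1.0
    sd = d.std(ddof=1)
    if sd == 0:
        # constant nonzero shift: infinite F, p -> 0
        return float("inf"), 0.0
    t = d.mean() / (sd / math.sqrt(n))
    f = t * t
    p = float(stats.f.sf(f, 1, n - 1))
    return float(f), p
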