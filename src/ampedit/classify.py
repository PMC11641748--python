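"""Rule-based diagnosis of false editing from genetic variation.

A locus flagged by the dual-window screen is interpreted by comparing the
sgRNA-free control allele table with the treated one.  Three artifact
patterns are distinguished:

* ``SNP`` -- many low-frequency substitution-only control alleles near the
  cut site (population polymorphism);
* ``DIVERGENT_HOMOLOG`` -- a single high-frequency substitution-only
  control allele that reappears at a matching frequency in the treated
  sample (a second co-amplified allele, e.g. from a sex-chromosome
  homolog; amplicon data cannot prove the chromosomal origin, so the label
  states only the allele pattern);
* ``REPEAT`` -- apparent editing inside the 2-nt window of the sgRNA-free
  control, or several indel-bearing control allele families: the hallmark
  of co-amplified repetitive/paralogous loci.

Rules are applied in a fixed order; the result never depends on the row
order of the allele tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .quant import AlleleRecord, AlleleTable
from .windows import DualWindowResult, ThresholdSpec

LABELS = ("NO_ARTIFACT", "SNP", "DIVERGENT_HOMOLOG", "REPEAT", "UNCLASSIFIED")


@dataclass(frozen=True)
class ClassifierParams:
    """Decision-rule parameters (fractions unless noted).

    ``noise_floor`` separates sequencing error from true variation signal;
    ``major_allele_floor`` splits a single divergent haplotype from a
    cloud of SNP alleles; ``freq_match_tol_pp`` is the control/treated
    allele-frequency agreement required to call a shared haplotype.
    """

    noise_floor: float = 0.02
    major_allele_floor: float = 0.10
    freq_match_tol_pp: float = 10.0


@dataclass
class VariationCall:
    label: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label != "NO_ARTIFACT" and not self.evidence:
            raise ValueError("evidence required for any non-trivial call")


def _modified(records: Sequence[AlleleRecord]) -> list[AlleleRecord]:
    return [r for r in records if r.modified_in_window]


def classify_locus(
    control_dual: DualWindowResult,
    control_alleles: AlleleTable,
    treated_alleles: AlleleTable | None,
    threshold: ThresholdSpec,
    params: ClassifierParams | None = None,
) -> VariationCall:
    """Classify one locus from its control (and optionally treated) tables.

    Decision order: no-artifact shortcut, repeat, divergent homolog, SNP,
    unclassified.  The repeat rule precedes the homolog rule because false
    editing inside the 2-nt window of an sgRNA-free sample is its
    distinguishing signal.
    """
    params = params or ClassifierParams()
    if treated_alleles is not None and control_alleles.span != treated_alleles.span:
        raise ValueError(
            f"allele tables span different intervals: {control_alleles.span} vs {treated_alleles.span}"
        )

    mod = _modified(control_alleles.records)
    mod_total = sum(r.frequency for r in mod)

    # (1) concordant windows and a quiet narrow window: nothing to explain
    if control_dual.delta_pp <= threshold.value_pp and control_dual.aee2 <= params.noise_floor:
        return VariationCall("NO_ARTIFACT", {"control_delta_pp": control_dual.delta_pp})

    evidence = {
        "control_aee2": control_dual.aee2,
        "control_aee20": control_dual.aee20,
        "control_delta_pp": control_dual.delta_pp,
        "n_modified_control_alleles": len(mod),
        "modified_control_frequency": mod_total,
    }

    # (2) repeats: "editing" without sgRNA in the narrow window, or
    # multiple indel-bearing allele families in the control
    indel_families = [r for r in mod if r.has_indel]
    if control_dual.aee2 > params.noise_floor or len(indel_families) >= 2:
        evidence["n_indel_families"] = len(indel_families)
        return VariationCall("REPEAT", evidence)

    # (3) one dominant substitution-only control allele mirrored in the
    # treated sample at a matching frequency
    major = [r for r in mod if r.substitution_only and r.frequency > params.major_allele_floor]
    if len(major) == 1 and treated_alleles is not None:
        ctrl = major[0]
        for t in treated_alleles.records:
            if (
                t.aligned_sequence == ctrl.aligned_sequence
                and abs(t.frequency - ctrl.frequency) * 100.0 <= params.freq_match_tol_pp
            ):
                evidence["control_allele_frequency"] = ctrl.frequency
                evidence["treated_allele_frequency"] = t.frequency
                evidence["allele"] = ctrl.aligned_sequence
                return VariationCall("DIVERGENT_HOMOLOG", evidence)

    # (4) a cloud of minor substitution-only alleles: population SNPs
    if (
        mod
        and all(r.substitution_only for r in mod)
        and all(r.frequency < params.major_allele_floor for r in mod)
        and mod_total > params.noise_floor
    ):
        evidence["allele_frequencies"] = [round(r.frequency, 4) for r in mod]
        return VariationCall("SNP", evidence)

    return VariationCall("UNCLASSIFIED", evidence)


def corrected_efficiency(
    treated_alleles: AlleleTable,
    control_alleles: AlleleTable,
    width: int = 20,
    params: ClassifierParams | None = None,
) -> float:
    """Treated modified-read fraction after removing control-matched alleles.

    Any treated allele whose spanning sequence also appears in the control
    above the noise floor is counted as pre-existing variation rather than
    editing.  The corrected value can never exceed the uncorrected AEE.
    """
    params = params or ClassifierParams()
    if width not in (2, 20):
        raise ValueError("width must be 2 or 20 (the analysis windows)")
    if treated_alleles.span != control_alleles.span:
        raise ValueError("allele tables span different intervals")
    control_seqs = {
        r.aligned_sequence for r in control_alleles.records if r.frequency > params.noise_floor
    }
    flag = (lambda r: r.modified_w2) if width == 2 else (lambda r: r.modified_w20)
    kept = sum(
        r.count for r in treated_alleles.records if flag(r) and r.aligned_sequence not in control_seqs
    )
    return kept / treated_alleles.n_aligned


def classification_report(
    calls: Sequence[VariationCall], truths: Sequence[str]
) -> tuple[pd.DataFrame, float]:
    """Confusion matrix (rows = planted class) and overall accuracy."""
    if not calls:
        raise ValueError("no calls to score")
    if len(calls) != len(truths):
        raise ValueError("calls and truths differ in length")
    for t in truths:
        if t not in LABELS:
            raise ValueError(f"unknown planted class {t!r}")
    matrix = pd.DataFrame(0, index=list(LABELS), columns=list(LABELS))
    for call, truth in zip(calls, truths):
        matrix.loc[truth, call.label] += 1
    accuracy = float(pd.Series([c.label == t for c, t in zip(calls, truths)]).mean())
    return matrix, accuracy
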