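"""Pre-configured study conditions mirroring the source experiments.

Each function here fixes the simulation parameters of one analysis --
the positive-control threshold derivation, the 224-sgRNA dual-window
cohort, the three genetic-variation case studies, the classifier
recovery benchmark, the GUIDE-seq planted-site benchmark and the
expression-vs-editing correlation -- and runs the corresponding pipeline
stage.  The numbered scripts under ``analysis/``, the test suite and the
acceptance script all call these functions, so the reported numbers come
from one code path.

Problem sizes are desk scale: enough reads that binomial noise is well
inside the tolerances being checked, small enough that every study runs
in seconds on one core.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import (
    VariationCall,
    classification_report,
    classify_locus,
    corrected_efficiency,
)
from .expression import correlate_expression_editing, normalize_counts
from .guideseq import (
    DsodnSpec,
    GenomeIndex,
    cluster_sites,
    find_dsodn_reads,
    offtarget_report,
    score_site_vs_guide,
)
from .pipeline import analyze_sample
from .quant import Amplicon, GuideSpec, cut_site
from .simulate import (
    DEFAULT_DSODN,
    HomologSpec,
    ParalogSpec,
    PlantedSite,
    ScenarioSpec,
    SnpSpec,
    divergent_homolog,
    make_amplicon,
    simulate_expression_editing_table,
    simulate_guideseq,
    simulate_paired_samples,
    simulate_reads,
)
from .windows import (
    ThresholdSpec,
    arcsine_transform,
    compare_window_distributions,
    derive_threshold,
    group_sgrnas,
    levene_test,
)


def _alt_base(ref_base: str) -> str:
    return {"A": "G", "C": "T", "G": "A", "T": "C", "N": "A"}[ref_base]


def snp_at(amplicon: Amplicon, guide: GuideSpec, offset: int, freq: float) -> SnpSpec:
    pos = cut_site(guide, amplicon) + offset
    return SnpSpec(offset=offset, alt=_alt_base(amplicon.sequence[pos]), carrier_freq=freq)


def _substituted(amplicon: Amplicon, guide: GuideSpec, offsets: Sequence[int]) -> str:
    site = cut_site(guide, amplicon)
    chars = list(amplicon.sequence)
    for off in offsets:
        chars[site + off] = _alt_base(chars[site + off])
    return "".join(chars)


def _deleted_at_cut(amplicon: Amplicon, guide: GuideSpec, length: int = 2) -> str:
    site = cut_site(guide, amplicon)
    start = site - math.ceil(length / 2)
    return amplicon.sequence[:start] + amplicon.sequence[start + length :]


# ---------------------------------------------------------------------------
# Parameter recovery (clean editing, no variation)


def recovery_study(seed: int, n_reads: int = 10000, edit_fraction: float = 0.41,
                   error_rate: float = 0.001) -> dict:
    """Estimate a known editing fraction from a clean simulated sample."""
    amplicon, guide = make_amplicon(250, 0.5, seed=seed)
    scenario = ScenarioSpec(edit_fraction=edit_fraction, error_rate=error_rate,
                            n_reads=n_reads, seed=seed + 1)
    reads, truths = simulate_reads(amplicon, guide, scenario)
    sample = analyze_sample(reads, amplicon, guide)
    true_edited = sum(t.edited for t in truths) / len(truths)
    return {
        "aee2": sample.dual.aee2,
        "aee20": sample.dual.aee20,
        "true_edit_fraction": edit_fraction,
        "seeded_edited_fraction": true_edited,
        "abs_error": abs(sample.dual.aee2 - edit_fraction),
        "n_reads": n_reads,
    }


# ---------------------------------------------------------------------------
# Window-nesting monotonicity over random scenarios


def random_scenario(amplicon: Amplicon, guide: GuideSpec, rng: np.random.Generator,
                    n_reads: int = 150) -> ScenarioSpec:
    """A randomised mixed scenario used for the monotonicity sweep."""
    snps = tuple(
        snp_at(amplicon, guide, off, float(rng.uniform(0.02, 0.4)))
        for off in rng.choice([o for o in range(-9, 10) if o not in (-1, 0)],
                              size=int(rng.integers(0, 3)), replace=False)
    )
    homolog = None
    if rng.random() < 0.3:
        offsets = rng.choice([o for o in range(-9, 10) if o not in (-1, 0)], size=3, replace=False)
        homolog = HomologSpec(_substituted(amplicon, guide, offsets), float(rng.uniform(0.1, 0.4)))
    paralogs = ()
    if rng.random() < 0.3:
        paralogs = (ParalogSpec(_deleted_at_cut(amplicon, guide, int(rng.integers(1, 4))),
                                float(rng.uniform(0.1, 0.4))),)
    return ScenarioSpec(
        edit_fraction=float(rng.uniform(0, 0.8)),
        snp_spec=snps,
        homolog_spec=homolog,
        paralog_spec=paralogs,
        error_rate=float(rng.uniform(0, 0.003)),
        n_reads=n_reads,
        seed=int(rng.integers(2**31)),
    )


def monotonicity_study(seed: int, n_scenarios: int = 100) -> dict:
    """AEE(2) <= AEE(20) must hold on every random scenario."""
    rng = np.random.default_rng(seed)
    violations = 0
    max_delta = 0.0
    for i in range(n_scenarios):
        amplicon, guide = make_amplicon(160, float(rng.uniform(0.35, 0.65)), seed=int(rng.integers(2**31)))
        scenario = random_scenario(amplicon, guide, rng)
        reads, _ = simulate_reads(amplicon, guide, scenario)
        dual = analyze_sample(reads, amplicon, guide).dual
        if dual.aee2 > dual.aee20 + 1e-12:
            violations += 1
        max_delta = max(max_delta, dual.delta_pp)
    return {"n_scenarios": n_scenarios, "violations": violations, "max_delta_pp": max_delta}


# ---------------------------------------------------------------------------
# The three genetic-variation case studies


def snp_case(seed: int, n_reads: int = 6000) -> dict:
    """Single common SNP 8 nt upstream of the cut: wide-window-only signal."""
    amplicon, guide = make_amplicon(240, 0.5, seed=seed)
    base = ScenarioSpec(snp_spec=(snp_at(amplicon, guide, -8, 0.49),),
                        error_rate=0.001, n_reads=n_reads, seed=seed)
    control, treated, truth = simulate_paired_samples(amplicon, guide, base, treated_edit_fraction=0.10)
    return _paired_case(amplicon, guide, control, treated, truth)


def homolog_case(seed: int, n_reads: int = 6000) -> dict:
    """One divergent allele at 21.6%, substitutions only, shared by both samples."""
    amplicon, guide = make_amplicon(240, 0.5, seed=seed)
    hom = divergent_homolog(amplicon, guide, offsets=(-7, -3, 4, 8), seed=seed)
    base = ScenarioSpec(homolog_spec=replace(hom, frequency=0.216),
                        error_rate=0.001, n_reads=n_reads, seed=seed)
    control, treated, truth = simulate_paired_samples(amplicon, guide, base, treated_edit_fraction=0.214)
    return _paired_case(amplicon, guide, control, treated, truth)


def repeat_case(seed: int, n_reads: int = 6000) -> dict:
    """Two co-amplified repeat families; one diverges inside the 2-nt window."""
    amplicon, guide = make_amplicon(240, 0.5, seed=seed)
    paralogs = (
        ParalogSpec(_deleted_at_cut(amplicon, guide, 2), weight=0.106),
        ParalogSpec(_substituted(amplicon, guide, (-9, -6, 5, 8)), weight=0.796),
    )
    base = ScenarioSpec(paralog_spec=paralogs, error_rate=0.001, n_reads=n_reads, seed=seed)
    control, treated, truth = simulate_paired_samples(amplicon, guide, base, treated_edit_fraction=0.10)
    return _paired_case(amplicon, guide, control, treated, truth)


def _paired_case(amplicon, guide, control, treated, truth) -> dict:
    threshold = ThresholdSpec(value_pp=10.0, provenance="fixed")
    ctrl = analyze_sample(control, amplicon, guide)
    trt = analyze_sample(treated, amplicon, guide)
    call = classify_locus(ctrl.dual, ctrl.alleles, trt.alleles, threshold)
    corrected = corrected_efficiency(trt.alleles, ctrl.alleles, width=20)
    return {
        "amplicon": amplicon,
        "guide": guide,
        "control": ctrl,
        "treated": trt,
        "control_reads": control,
        "treated_reads": treated,
        "truth": truth,
        "call": call,
        "corrected_efficiency_w20": corrected,
    }


def variation_cases_study(seed: int) -> dict:
    """Run all three variation case studies and summarise the key numbers."""
    snp = snp_case(seed)
    hom = homolog_case(seed + 1)
    rep = repeat_case(seed + 2)
    hom_major = [
        r for r in hom["control"].alleles.records
        if r.modified_in_window and r.substitution_only and r.frequency > 0.10
    ]
    return {
        "snp": snp,
        "homolog": hom,
        "repeat": rep,
        "summary": {
            "snp_control_aee2_pct": 100 * snp["control"].dual.aee2,
            "snp_control_aee20_pct": 100 * snp["control"].dual.aee20,
            "snp_label": snp["call"].label,
            "homolog_control_aee20_pct": 100 * hom["control"].dual.aee20,
            "homolog_major_allele_pct": 100 * hom_major[0].frequency if hom_major else float("nan"),
            "homolog_n_major_alleles": len(hom_major),
            "homolog_label": hom["call"].label,
            "repeat_control_aee2_pct": 100 * rep["control"].dual.aee2,
            "repeat_control_aee20_pct": 100 * rep["control"].dual.aee20,
            "repeat_label": rep["call"].label,
        },
    }


# ---------------------------------------------------------------------------
# Positive-control threshold derivation


def positive_control_surrogate_study(seed: int, n_reads: int = 50000) -> dict:
    """Simulated stand-in for the positive-control sample.

    True editing at 41% plus a flanking SNP tuned so the wide window reads
    ~51% -- the treated-sample pattern from which the 10-pp threshold is
    derived (largest window discrepancy, rounded to whole points).
    """
    amplicon, guide = make_amplicon(250, 0.5, seed=seed)
    # wide-window surplus = (1 - e) * carrier = 0.1012 -> carrier 0.1715
    scenario = ScenarioSpec(edit_fraction=0.41,
                            snp_spec=(snp_at(amplicon, guide, -6, 0.1715),),
                            error_rate=0.0, n_reads=n_reads, seed=seed + 1)
    reads, _ = simulate_reads(amplicon, guide, scenario)
    dual = analyze_sample(reads, amplicon, guide).dual
    threshold = derive_threshold([dual])
    return {
        "aee2_pct": 100 * dual.aee2,
        "aee20_pct": 100 * dual.aee20,
        "delta_pp": dual.delta_pp,
        "threshold_pp": threshold.value_pp,
        "threshold": threshold,
        "n_reads": n_reads,
    }


# ---------------------------------------------------------------------------
# Dual-window cohort (grouping + proportion statistics)


def cohort_study(seed: int, n_loci: int = 224, variation_fraction: float = 52 / 224,
                 n_reads: int = 150) -> dict:
    """A cohort of sgRNA loci, a fraction of which carry flanking variation.

    Loci are screened with the dual-window contrast at the 10-pp
    threshold, grouped, and compared with the arcsine/Levene/repeated-
    measures machinery.
    """
    rng = np.random.default_rng(seed)
    n_var = round(n_loci * variation_fraction)
    rows = []
    for i in range(n_loci):
        amplicon, guide = make_amplicon(160, 0.5, seed=int(rng.integers(2**31)))
        kinds = ("snp", "homolog", "repeat")
        if i < n_var:
            kind = kinds[i % 3]
            if kind == "snp":
                offs = rng.choice([o for o in range(-9, 10) if o not in (-1, 0)], size=3, replace=False)
                snps = tuple(snp_at(amplicon, guide, int(o), float(rng.uniform(0.08, 0.2))) for o in offs)
                base = ScenarioSpec(snp_spec=snps, error_rate=0.0005, n_reads=n_reads,
                                    seed=int(rng.integers(2**31)))
            elif kind == "homolog":
                offsets = rng.choice([o for o in range(-9, 10) if o not in (-1, 0)], size=3, replace=False)
                hom = HomologSpec(_substituted(amplicon, guide, offsets), float(rng.uniform(0.2, 0.5)))
                base = ScenarioSpec(homolog_spec=hom, error_rate=0.0005, n_reads=n_reads,
                                    seed=int(rng.integers(2**31)))
            else:
                par = ParalogSpec(_substituted(amplicon, guide, (-8, -5, 6)), float(rng.uniform(0.2, 0.5)))
                base = ScenarioSpec(paralog_spec=(par,), error_rate=0.0005, n_reads=n_reads,
                                    seed=int(rng.integers(2**31)))
        else:
            kind = "clean"
            base = ScenarioSpec(error_rate=0.0005, n_reads=n_reads, seed=int(rng.integers(2**31)))
        scenario = replace(base, edit_fraction=float(rng.uniform(0.1, 0.7)))
        reads, _ = simulate_reads(amplicon, guide, scenario)
        dual = analyze_sample(reads, amplicon, guide).dual
        rows.append({"locus": f"sgRNA_{i:03d}", "kind": kind,
                     "aee2": dual.aee2, "aee20": dual.aee20, "delta_pp": dual.delta_pp})
    table = pd.DataFrame(rows)
    threshold = ThresholdSpec(10.0, "fixed")
    summary, labels = group_sgrnas(list(zip(table.aee2, table.aee20)), threshold)
    table["group"] = labels

    stats_out = {}
    t2 = arcsine_transform(table.aee2.values)
    t20 = arcsine_transform(table.aee20.values)
    for group in ("below", "above"):
        mask = (table.group == group).values
        if mask.sum() >= 3:
            w, p_lev = levene_test([t2[mask], t20[mask]])
            f, p_rm = compare_window_distributions(t2[mask], t20[mask])
            stats_out[group] = {"n": int(mask.sum()), "levene_W": w, "levene_p": p_lev,
                                "rm_anova_F": f, "rm_anova_p": p_rm}
    return {
        "table": table,
        "group_summary": summary,
        "fraction_below": summary.fraction_below,
        "stats": stats_out,
        "threshold_pp": threshold.value_pp,
    }


# ---------------------------------------------------------------------------
# Classifier recovery benchmark


def classifier_locus(kind: str, rng: np.random.Generator, n_reads: int = 300) -> dict:
    """One simulated locus of a planted artifact class, control + treated."""
    amplicon, guide = make_amplicon(200, 0.5, seed=int(rng.integers(2**31)))
    offsets_pool = [o for o in range(-9, 10) if o not in (-1, 0)]
    if kind == "NO_ARTIFACT":
        base = ScenarioSpec(error_rate=0.001, n_reads=n_reads, seed=int(rng.integers(2**31)))
    elif kind == "SNP":
        k = int(rng.integers(3, 5))
        offs = rng.choice(offsets_pool, size=k, replace=False)
        snps = tuple(snp_at(amplicon, guide, int(o), float(rng.uniform(0.05, 0.09))) for o in offs)
        base = ScenarioSpec(snp_spec=snps, error_rate=0.001, n_reads=n_reads,
                            seed=int(rng.integers(2**31)))
    elif kind == "DIVERGENT_HOMOLOG":
        offs = rng.choice(offsets_pool, size=int(rng.integers(2, 5)), replace=False)
        hom = HomologSpec(_substituted(amplicon, guide, offs), float(rng.uniform(0.2, 0.5)))
        base = ScenarioSpec(homolog_spec=hom, error_rate=0.001, n_reads=n_reads,
                            seed=int(rng.integers(2**31)))
    elif kind == "REPEAT":
        par = ParalogSpec(_deleted_at_cut(amplicon, guide, int(rng.integers(2, 5))),
                          float(rng.uniform(0.15, 0.6)))
        base = ScenarioSpec(paralog_spec=(par,), error_rate=0.001, n_reads=n_reads,
                            seed=int(rng.integers(2**31)))
    else:
        raise ValueError(f"no generator for planted class {kind!r}")
    control, treated, truth = simulate_paired_samples(
        amplicon, guide, base, treated_edit_fraction=float(rng.uniform(0.2, 0.6))
    )
    return {"amplicon": amplicon, "guide": guide, "control": control,
            "treated": treated, "truth": truth, "kind": kind}


def classifier_benchmark(seed: int, n_per_class: int = 50, n_reads: int = 300) -> dict:
    """Recovery of planted artifact classes over simulated locus cohorts."""
    rng = np.random.default_rng(seed)
    classes = ("NO_ARTIFACT", "SNP", "DIVERGENT_HOMOLOG", "REPEAT")
    threshold = ThresholdSpec(10.0, "fixed")
    calls: list[VariationCall] = []
    truths: list[str] = []
    for kind in classes:
        for _ in range(n_per_class):
            locus = classifier_locus(kind, rng, n_reads=n_reads)
            ctrl = analyze_sample(locus["control"], locus["amplicon"], locus["guide"])
            trt = analyze_sample(locus["treated"], locus["amplicon"], locus["guide"])
            calls.append(classify_locus(ctrl.dual, ctrl.alleles, trt.alleles, threshold))
            truths.append(kind)
    matrix, accuracy = classification_report(calls, truths)
    return {"confusion": matrix, "accuracy": accuracy,
            "n_loci": len(truths), "n_per_class": n_per_class}


# ---------------------------------------------------------------------------
# GUIDE-seq benchmark


def guideseq_run(seed: int, genome_length: int = 20000, on_target_reads: int = 600,
                 n_background: int = 200) -> dict:
    """One planted-site GUIDE-seq simulation analysed end to end."""
    rng = np.random.default_rng(seed)
    amplicon, guide = make_amplicon(120, 0.5, seed=int(rng.integers(2**31)))
    n_off = int(rng.integers(1, 4))
    margin = 400
    positions = []
    while len(positions) < n_off + 1:
        cand = int(rng.integers(margin, genome_length - margin))
        if all(abs(cand - p) > 300 for p in positions):
            positions.append(cand)
    sites = [PlantedSite(positions[0], "+", 0, on_target_reads)]
    for p in positions[1:]:
        sites.append(PlantedSite(p, "+" if rng.random() < 0.5 else "-",
                                 int(rng.integers(3, 6)), int(rng.integers(5, 21))))
    genome, reads, truth = simulate_guideseq(
        genome_length, sites, guide.protospacer, seed=int(rng.integers(2**31)),
        n_background_reads=n_background,
    )
    dsodn = DsodnSpec(DEFAULT_DSODN, max_mismatches=1)
    tagged = find_dsodn_reads(reads, dsodn)
    index = GenomeIndex(genome, k=12)
    found = cluster_sites(tagged, index)
    on_cut = int(truth.loc[truth.mismatches == 0, "cut_position"].iloc[0])
    records = [score_site_vs_guide(s, genome, guide, on_target_position=on_cut) for s in found]
    table, summary = offtarget_report(records, total_reads=len(reads), tagged_reads=len(tagged))

    matched = 0
    counts_exact = True
    for _, row in truth.iterrows():
        hit = [s for s in found if abs(s.position - row.cut_position) <= 10]
        if hit:
            matched += 1
            if hit[0].read_count != row.read_count:
                counts_exact = False
    spurious = sum(
        1 for s in found if not any(abs(s.position - c) <= 10 for c in truth.cut_position)
    )
    return {"truth": truth, "sites": found, "table": table, "summary": summary,
            "n_planted": len(sites), "n_recovered": matched,
            "counts_exact": counts_exact, "n_spurious": spurious}


def guideseq_benchmark(seed: int, n_simulations: int = 20) -> dict:
    """Planted-site recall / spurious-site count over seeded simulations."""
    rng = np.random.default_rng(seed)
    planted = recovered = spurious = 0
    counts_exact = True
    fractions = []
    for _ in range(n_simulations):
        run = guideseq_run(int(rng.integers(2**31)))
        planted += run["n_planted"]
        recovered += run["n_recovered"]
        spurious += run["n_spurious"]
        counts_exact = counts_exact and run["counts_exact"]
        fractions.append(run["summary"]["off_target_fraction_of_total"])
    return {
        "n_simulations": n_simulations,
        "planted_sites": planted,
        "recovered_sites": recovered,
        "recall": recovered / planted,
        "spurious_sites": spurious,
        "read_counts_exact": counts_exact,
        "mean_off_target_fraction_pct": 100 * float(np.mean(fractions)),
    }


def offtarget_fraction_study(seed: int) -> dict:
    """Deep-library off-target accounting at the published read scale.

    One on-target site (600 tagged reads), one weak off-target (5 reads,
    4 protospacer mismatches) in a library of 65,517 reads total -- the
    regime where off-target incorporation measures in the 1e-4 range of
    total reads.
    """
    rng = np.random.default_rng(seed)
    genome_length = 30000
    amplicon, guide = make_amplicon(120, 0.5, seed=int(rng.integers(2**31)))
    on_pos, off_pos = 8000, 21000
    sites = [PlantedSite(on_pos, "+", 0, 600), PlantedSite(off_pos, "+", 4, 5)]
    n_background = 65517 - 605
    genome, reads, truth = simulate_guideseq(
        genome_length, sites, guide.protospacer,
        n_background_reads=n_background, seed=int(rng.integers(2**31)),
    )
    tagged = find_dsodn_reads(reads, DsodnSpec(DEFAULT_DSODN, max_mismatches=1))
    found = cluster_sites(tagged, GenomeIndex(genome, k=12))
    on_cut = int(truth.loc[truth.mismatches == 0, "cut_position"].iloc[0])
    records = [score_site_vs_guide(s, genome, guide, on_target_position=on_cut) for s in found]
    table, summary = offtarget_report(records, total_reads=len(reads), tagged_reads=len(tagged))
    return {
        "table": table,
        "summary": summary,
        "total_reads": len(reads),
        "off_target_fraction_pct": 100 * summary["off_target_fraction_of_total"],
        "on_target_reads": summary["on_target_reads"],
        "off_target_reads": summary["off_target_reads"],
    }


# ---------------------------------------------------------------------------
# Expression-vs-editing correlation


def expression_study(seed: int, n_genes: int = 50, correlation_target: float = 0.25,
                     n_recovery_seeds: int = 30) -> dict:
    """Rank correlation between expression and narrow-window editing.

    One paper-scale draw (50 genes, six replicates) plus a multi-seed mean
    to show the generator actually hits the requested rank correlation.
    """
    counts, editing = simulate_expression_editing_table(n_genes, correlation_target, seed=seed)
    expr = normalize_counts(counts)
    result, pairs, unmatched = correlate_expression_editing(expr, editing)
    rhos = []
    for k in range(n_recovery_seeds):
        c, e = simulate_expression_editing_table(n_genes, correlation_target, seed=seed + 1000 + k)
        rhos.append(correlate_expression_editing(normalize_counts(c), e)[0].rho)
    return {
        "rho": result.rho,
        "p_value": result.p_value,
        "n": result.n,
        "pairs": pairs,
        "unmatched": unmatched,
        "mean_recovered_rho": float(np.mean(rhos)),
        "correlation_target": correlation_target,
        "n_recovery_seeds": n_recovery_seeds,
    }
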