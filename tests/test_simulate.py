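"""Synthetic-data generator: determinism, composition and ground truth."""

import numpy as np
import pytest

from ampedit import (
    DEFAULT_DSODN,
    HomologSpec,
    ParalogSpec,
    PlantedSite,
    ScenarioSpec,
    SnpSpec,
    cut_site,
    divergent_homolog,
    make_amplicon,
    simulate_expression_editing_table,
    simulate_guideseq,
    simulate_paired_samples,
    simulate_reads,
)
from ampedit.expression import spearman


class TestMakeAmplicon:
    def test_planted_protospacer_is_unique_with_pam(self):
        amplicon, guide = make_amplicon(250, 0.5, seed=1)
        assert len(amplicon) == 250
        assert amplicon.sequence.count(guide.protospacer) == 1
        footprint_end = guide.protospacer_start + 23
        assert amplicon.sequence[footprint_end - 2 : footprint_end] == "GG"
        guide.validate_against(amplicon)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 80"):
            make_amplicon(79)

    def test_same_seed_is_byte_identical(self):
        a1, g1 = make_amplicon(250, 0.5, seed=9)
        a2, g2 = make_amplicon(250, 0.5, seed=9)
        assert a1.sequence == a2.sequence
        assert g1 == g2


class TestSimulateReads:
    def test_null_scenario_reproduces_the_reference(self):
        amplicon, guide = make_amplicon(120, 0.5, seed=2)
        reads, truths = simulate_reads(
            amplicon, guide, ScenarioSpec(edit_fraction=0.0, error_rate=0.0, n_reads=50, seed=1)
        )
        assert all(r.sequence == amplicon.sequence for r in reads)
        assert all(not t.edited and t.origin == "primary" for t in truths)

    def test_edited_count_equals_truth_enumeration(self):
        """The binomial draw, re-enumerated from truth records, is stable per seed."""
        amplicon, guide = make_amplicon(120, 0.5, seed=2)
        scn = ScenarioSpec(edit_fraction=0.5, n_reads=10, seed=42)
        _, t1 = simulate_reads(amplicon, guide, scn)
        _, t2 = simulate_reads(amplicon, guide, scn)
        assert [t.edited for t in t1] == [t.edited for t in t2]
        assert 0 <= sum(t.edited for t in t1) <= 10

    def test_every_read_has_exactly_one_truth_record(self):
        amplicon, guide = make_amplicon(120, 0.5, seed=2)
        reads, truths = simulate_reads(
            amplicon, guide, ScenarioSpec(edit_fraction=0.3, n_reads=200, seed=5)
        )
        assert len(reads) == len(truths) == 200
        assert {r.id for r in reads} == {t.read_id for t in truths}

    def test_homolog_fraction_within_binomial_error(self):
        amplicon, guide = make_amplicon(160, 0.5, seed=4)
        hom = divergent_homolog(amplicon, guide, offsets=(-7, 5), seed=1)
        n = 4000
        scn = ScenarioSpec(
            homolog_spec=HomologSpec(hom.sequence, 0.216), n_reads=n, seed=8
        )
        _, truths = simulate_reads(amplicon, guide, scn)
        frac = sum(t.origin == "homolog" for t in truths) / n
        assert abs(frac - 0.216) <= 3 * np.sqrt(0.216 * 0.784 / n)

    def test_origin_composition_tallies_to_n_reads(self):
        amplicon, guide = make_amplicon(160, 0.5, seed=4)
        par = ParalogSpec(amplicon.sequence[:70] + amplicon.sequence[72:], 0.3)
        hom = divergent_homolog(amplicon, guide, offsets=(-5,), seed=2)
        scn = ScenarioSpec(
            homolog_spec=HomologSpec(hom.sequence, 0.2),
            paralog_spec=(par,),
            n_reads=500,
            seed=3,
        )
        _, truths = simulate_reads(amplicon, guide, scn)
        origins = {}
        for t in truths:
            origins[t.origin] = origins.get(t.origin, 0) + 1
        assert sum(origins.values()) == 500
        assert set(origins) <= {"primary", "homolog", "paralog_0"}

    def test_edited_truths_always_carry_a_cut_covering_indel(self):
        amplicon, guide = make_amplicon(160, 0.5, seed=4)
        cut = cut_site(guide, amplicon)
        _, truths = simulate_reads(
            amplicon, guide, ScenarioSpec(edit_fraction=0.6, n_reads=300, seed=6)
        )
        for t in truths:
            if not t.edited:
                continue
            indels = [e for e in t.events if e.startswith(("del:", "ins:"))]
            assert len(indels) == 1
            ev = indels[0]
            if ev.startswith("del:"):
                start, end = map(int, ev[4:].split("-"))
                assert start <= cut <= end
            else:
                anchor = int(ev.split(":")[1])
                assert anchor == cut

    def test_snp_offsets_inside_narrow_window_rejected(self):
        amplicon, guide = make_amplicon(160, 0.5, seed=4)
        scn = ScenarioSpec(snp_spec=(SnpSpec(0, "A", 0.5),), n_reads=10, seed=1)
        with pytest.raises(ValueError, match="2-nt quantification window"):
            simulate_reads(amplicon, guide, scn)

    def test_identical_paralog_warns_but_runs(self):
        amplicon, guide = make_amplicon(160, 0.5, seed=4)
        scn = ScenarioSpec(paralog_spec=(ParalogSpec(amplicon.sequence, 0.2),), n_reads=10, seed=1)
        with pytest.warns(UserWarning, match="identical"):
            simulate_reads(amplicon, guide, scn)


class TestPairedSamples:
    def test_control_is_never_edited_and_shares_variation(self):
        amplicon, guide = make_amplicon(160, 0.5, seed=4)
        hom = divergent_homolog(amplicon, guide, offsets=(-6, 7), seed=3)
        base = ScenarioSpec(homolog_spec=HomologSpec(hom.sequence, 0.3), n_reads=400, seed=17)
        control, treated, truth = simulate_paired_samples(amplicon, guide, base, 0.4)
        ctrl = truth[truth["sample"] == "control"]
        trt = truth[truth["sample"] == "treated"]
        assert not ctrl.edited.any()
        assert trt.edited.any()
        # both samples draw homolog reads from the same spec
        assert (ctrl.origin == "homolog").mean() > 0.15
        assert (trt.origin == "homolog").mean() > 0.15


class TestGuideseqSimulator:
    def test_no_planted_sites_means_no_tagged_reads(self):
        _, guide = make_amplicon(120, 0.5, seed=1)
        genome, reads, truth = simulate_guideseq(5000, [], guide.protospacer, seed=1)
        assert truth.empty
        assert all(DEFAULT_DSODN not in r.sequence for r in reads)

    def test_planted_sites_produce_stated_read_counts(self):
        _, guide = make_amplicon(120, 0.5, seed=1)
        sites = [PlantedSite(2000, "+", 0, 30), PlantedSite(4000, "-", 3, 5)]
        genome, reads, truth = simulate_guideseq(8000, sites, guide.protospacer, seed=2)
        assert truth.read_count.tolist() == [30, 5]
        from ampedit.quant import revcomp

        tagged = [
            r for r in reads
            if DEFAULT_DSODN in r.sequence or DEFAULT_DSODN in revcomp(r.sequence)
        ]
        assert len(tagged) == 35

    def test_same_seed_identical_reads(self):
        _, guide = make_amplicon(120, 0.5, seed=1)
        sites = [PlantedSite(2000, "+", 0, 10)]
        _, r1, _ = simulate_guideseq(8000, sites, guide.protospacer, seed=3)
        _, r2, _ = simulate_guideseq(8000, sites, guide.protospacer, seed=3)
        assert [(a.id, a.sequence) for a in r1] == [(b.id, b.sequence) for b in r2]

    def test_site_near_edge_rejected(self):
        _, guide = make_amplicon(120, 0.5, seed=1)
        with pytest.raises(ValueError, match="edge"):
            simulate_guideseq(8000, [PlantedSite(10, "+", 0, 5)], guide.protospacer, seed=1)


class TestExpressionSimulator:
    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            simulate_expression_editing_table(3, 0.2, seed=1)

    def test_correlation_target_bounds(self):
        with pytest.raises(ValueError, match="correlation_target"):
            simulate_expression_editing_table(50, 1.5, seed=1)

    def test_null_target_gives_rho_near_zero_over_seeds(self):
        rhos = []
        for seed in range(25):
            counts, editing = simulate_expression_editing_table(60, 0.0, seed=seed)
            rhos.append(spearman(np.log1p(counts).mean(axis=1).values, editing.values).rho)
        assert abs(np.mean(rhos)) < 0.08  # ~3 SE of the mean at n=60, 25 seeds
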