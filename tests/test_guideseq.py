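"""Tag detection, flank mapping, site clustering and guide scoring."""

import numpy as np
import pytest

from ampedit import (
    DEFAULT_DSODN,
    DsodnSpec,
    GenomeIndex,
    GuideSpec,
    IntegrationSite,
    PlantedSite,
    cluster_sites,
    find_dsodn_reads,
    make_amplicon,
    map_flank,
    offtarget_report,
    revcomp,
    score_site_vs_guide,
    simulate_guideseq,
)
from ampedit.guideseq import TaggedRead
from ampedit.simulate import SimRead, _random_seq

from oracles import hamming_occurrences

TAG = DEFAULT_DSODN


def _genome(rng, n=6000):
    return {"chr1": _random_seq(rng, n)}


class TestTagDetection:
    def test_flank_plus_tag_is_extracted(self, rng):
        flank = _random_seq(rng, 40)
        reads = [SimRead("r1", flank + TAG + _random_seq(rng, 30))]
        tagged = find_dsodn_reads(reads, DsodnSpec(TAG))
        assert len(tagged) == 1
        assert tagged[0].flank == flank
        assert tagged[0].tag_orientation == "+"

    def test_reverse_orientation_is_normalised(self, rng):
        flank = _random_seq(rng, 40)
        read = revcomp(flank + TAG + _random_seq(rng, 30))
        tagged = find_dsodn_reads([SimRead("r1", read)], DsodnSpec(TAG))
        assert len(tagged) == 1
        assert tagged[0].flank == flank
        assert tagged[0].tag_orientation == "-"

    def test_untagged_read_is_ignored(self, rng):
        tagged = find_dsodn_reads([SimRead("r1", _random_seq(rng, 150))], DsodnSpec(TAG))
        assert tagged == []

    def test_mismatch_budget_matches_hamming_enumeration(self, rng):
        flank = _random_seq(rng, 40)
        mutated = "A" + TAG[1:] if TAG[0] != "A" else "C" + TAG[1:]
        two_off = mutated[:5] + ("A" if mutated[5] != "A" else "C") + mutated[6:]
        for tag_variant, budget, expect in [(mutated, 1, True), (two_off, 1, False), (two_off, 2, True)]:
            read = flank + tag_variant + _random_seq(rng, 20)
            got = find_dsodn_reads([SimRead("r", read)], DsodnSpec(TAG, max_mismatches=budget))
            assert bool(got) == expect
            assert bool(hamming_occurrences(read, TAG, budget)) == expect

    def test_short_flank_dropped(self, rng):
        reads = [SimRead("r1", _random_seq(rng, 10) + TAG + _random_seq(rng, 60))]
        assert find_dsodn_reads(reads, DsodnSpec(TAG), min_flank=20) == []


class TestFlankMapping:
    def test_unique_flank_maps_once(self, rng):
        genome = _genome(rng)
        flank = genome["chr1"][1000:1040]
        placements = map_flank(flank, genome)
        assert len(placements) == 1
        assert (placements[0].start, placements[0].strand) == (1000, "+")
        assert placements[0].junction == 1040

    def test_duplicated_flank_reports_both_placements(self, rng):
        seq = _random_seq(rng, 3000)
        dup = _random_seq(rng, 45)
        genome = {"chr1": seq[:500] + dup + seq[500:1500] + dup + seq[1500:]}
        placements = map_flank(dup, genome)
        assert len(placements) == 2

    def test_reverse_strand_flank_found(self, rng):
        genome = _genome(rng)
        flank = revcomp(genome["chr1"][2000:2040])
        placements = map_flank(flank, genome)
        assert len(placements) == 1
        assert placements[0].strand == "-"
        assert placements[0].junction == 2000

    def test_mismatched_flank_agrees_with_full_scan(self, rng):
        """Seed-and-verify must equal the exhaustive both-strand scan."""
        genome = _genome(rng, 4000)
        index = GenomeIndex(genome, k=12)
        for trial in range(20):
            start = int(rng.integers(0, 3960))
            flank = list(genome["chr1"][start : start + 40])
            n_mm = int(rng.integers(0, 2))
            for pos in rng.choice(40, size=n_mm, replace=False):
                flank[pos] = "A" if flank[pos] != "A" else "G"
            flank = "".join(flank)
            if rng.random() < 0.5:
                flank = revcomp(flank)
            got = {(p.contig, p.start, p.strand) for p in index.map_flank(flank, 1)}
            fwd = hamming_occurrences(genome["chr1"], flank, 1)
            rev = hamming_occurrences(genome["chr1"], revcomp(flank), 1)
            expected = {("chr1", s, "+") for s in fwd} | {("chr1", s, "-") for s in rev}
            assert got == expected

    def test_empty_flank_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            map_flank("", _genome(rng))


class TestClustering:
    def _tagged_at(self, genome, positions):
        return [
            TaggedRead(f"r{i}", genome["chr1"][p - 40 : p], "+")
            for i, p in enumerate(positions)
        ]

    def test_nearby_junctions_merge(self, rng):
        genome = _genome(rng)
        index = GenomeIndex(genome)
        sites = cluster_sites(self._tagged_at(genome, [1000, 1001, 1003]), index)
        assert len(sites) == 1
        assert sites[0].read_count == 3
        assert sites[0].position == 1000

    def test_distant_junctions_stay_separate(self, rng):
        genome = _genome(rng)
        index = GenomeIndex(genome)
        sites = cluster_sites(
            self._tagged_at(genome, [1000, 1000, 1100, 1100]), index, min_reads=2
        )
        assert sorted(s.position for s in sites) == [1000, 1100]

    def test_min_reads_filter(self, rng):
        genome = _genome(rng)
        index = GenomeIndex(genome)
        assert cluster_sites(self._tagged_at(genome, [1500]), index, min_reads=2) == []


class TestScoring:
    def test_planted_on_target_scores_zero_mismatches(self, rng):
        _, guide = make_amplicon(120, 0.5, seed=5)
        genome, reads, truth = simulate_guideseq(
            8000, [PlantedSite(3000, "+", 0, 10)], guide.protospacer, seed=6
        )
        cut = int(truth.cut_position.iloc[0])
        site = IntegrationSite("chr_sim", cut, "+", 10)
        rec = score_site_vs_guide(site, genome, guide, on_target_position=cut)
        assert rec.n_mismatches == 0
        assert rec.is_on_target
        assert rec.has_pam

    def test_planted_mismatches_recovered_at_their_positions(self, rng):
        _, guide = make_amplicon(120, 0.5, seed=5)
        genome, reads, truth = simulate_guideseq(
            8000, [PlantedSite(3000, "-", 3, 10)], guide.protospacer, seed=7
        )
        cut = int(truth.cut_position.iloc[0])
        planted = [int(x) for x in truth.mismatch_offsets.iloc[0].split(";")]
        rec = score_site_vs_guide(IntegrationSite("chr_sim", cut, "+", 10), genome, guide)
        assert rec.n_mismatches == 3
        assert rec.mismatch_positions == planted
        assert not rec.is_on_target

    def test_random_locus_scores_many_mismatches(self, rng):
        _, guide = make_amplicon(120, 0.5, seed=5)
        genome = _genome(rng)
        rec = score_site_vs_guide(IntegrationSite("chr1", 3000, "+", 5), genome, guide)
        assert rec.n_mismatches >= 5


class TestReport:
    def test_fraction_arithmetic(self):
        on = IntegrationSite("chr1", 100, "+", 600)
        off = IntegrationSite("chr1", 900, "+", 5)
        records = []
        for site, is_on in ((on, True), (off, False)):
            from ampedit.guideseq import OfftargetRecord

            records.append(
                OfftargetRecord(site, "A" * 20, "TGG", "+", site.position, 0 if is_on else 3,
                                [], True, is_on)
            )
        table, summary = offtarget_report(records, total_reads=65517, tagged_reads=605)
        assert summary["off_target_reads"] == 5
        assert summary["off_target_fraction_of_total"] == pytest.approx(5 / 65517)
        assert summary["off_target_fraction_of_tagged"] == pytest.approx(5 / 605)
        assert len(table) == 2

    def test_empty_records_give_zero_fraction(self):
        table, summary = offtarget_report([], total_reads=100)
        assert table.empty
        assert summary["off_target_fraction_of_total"] == 0.0

    def test_zero_total_reads_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            offtarget_report([], total_reads=0)


class TestEndToEnd:
    def test_each_tagged_read_contributes_to_at_most_one_site(self):
        from ampedit.studies import guideseq_run

        run = guideseq_run(99)
        seen: set[str] = set()
        for site in run["sites"]:
            assert not (seen & set(site.read_ids))
            seen.update(site.read_ids)
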