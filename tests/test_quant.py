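"""Cut-site arithmetic, window classification, AEE and allele tables."""

import numpy as np
import pytest

from ampedit import (
    Amplicon,
    GuideSpec,
    QuantWindow,
    allele_table,
    classify_read,
    cut_site,
    make_amplicon,
    quantify,
    revcomp,
)
from ampedit.align import align_read


def _amp_with_guide(strand="+"):
    amplicon, guide = make_amplicon(200, 0.5, seed=3)
    if strand == "+":
        return amplicon, guide
    # re-express the same physical target on the reverse-complement amplicon
    flipped = Amplicon(id="amp_rc", sequence=revcomp(amplicon.sequence))
    start = len(amplicon) - (guide.protospacer_start + 20)
    minus = GuideSpec(
        protospacer=guide.protospacer,
        pam=guide.pam,
        strand="-",
        protospacer_start=start,
        cut_offset=guide.cut_offset,
    )
    return flipped, minus


def test_cut_site_plus_strand_arithmetic():
    amplicon, guide = _amp_with_guide("+")
    assert cut_site(guide, amplicon) == guide.protospacer_start + 17


def test_cut_site_minus_strand_matches_brute_force_strand_scan():
    """The minus-strand coordinate must mirror a direct search of both strands."""
    amplicon, guide = _amp_with_guide("-")
    seq = amplicon.sequence
    hit = revcomp(seq).find(guide.protospacer)
    assert hit >= 0
    # cut is 17 nt into the protospacer on the minus strand; map to forward coords
    cut_on_rc = hit + 17
    expected = len(seq) - cut_on_rc
    assert cut_site(guide, amplicon) == expected


def test_wrong_protospacer_is_an_error():
    amplicon, guide = _amp_with_guide("+")
    bad = GuideSpec(
        protospacer="A" * 20,
        pam=guide.pam,
        strand="+",
        protospacer_start=guide.protospacer_start,
    )
    with pytest.raises(ValueError, match="protospacer mismatch"):
        cut_site(bad, amplicon)


@pytest.fixture(scope="module")
def locus():
    amplicon, guide = make_amplicon(200, 0.5, seed=3)
    return amplicon, guide, cut_site(guide, amplicon)


def _sub_at(amplicon, pos):
    alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[amplicon.sequence[pos]]
    return amplicon.sequence[:pos] + alt + amplicon.sequence[pos + 1 :]


def _del_at(amplicon, start, length):
    return amplicon.sequence[:start] + amplicon.sequence[start + length :]


def test_substitution_near_cut_is_wide_window_only(locus):
    amplicon, guide, cut = locus
    read = _sub_at(amplicon, cut - 8)
    aln = align_read(read, amplicon.sequence)
    assert not classify_read(aln, QuantWindow(cut, 2), amplicon).modified
    assert classify_read(aln, QuantWindow(cut, 20), amplicon).modified


def test_cut_site_deletion_hits_both_windows(locus):
    amplicon, guide, cut = locus
    read = _del_at(amplicon, cut - 1, 1)
    aln = align_read(read, amplicon.sequence)
    assert classify_read(aln, QuantWindow(cut, 2), amplicon).modified
    assert classify_read(aln, QuantWindow(cut, 20), amplicon).modified


def test_deletion_overlap_rule_matches_interval_arithmetic(locus):
    """A deletion overlaps a window iff its interval crosses the bounds."""
    amplicon, guide, cut = locus
    # deletion of [cut-11, cut-9): clipped overlap with [cut-10, cut+10)
    read = _del_at(amplicon, cut - 11, 2)
    aln = align_read(read, amplicon.sequence)
    assert classify_read(aln, QuantWindow(cut, 20), amplicon).modified
    # brute-force check over every 2-nt deletion placement
    for start in range(cut - 30, cut + 28):
        read = _del_at(amplicon, start, 2)
        aln = align_read(read, amplicon.sequence)
        got = classify_read(aln, QuantWindow(cut, 20), amplicon).modified
        # expected: any score-equivalent placement of the deletion overlaps
        placements = {start}
        s = start
        while s > 0 and amplicon.sequence[s - 1] == amplicon.sequence[s + 1]:
            s -= 1
            placements.add(s)
        s = start
        while s + 2 < len(amplicon) and amplicon.sequence[s] == amplicon.sequence[s + 2]:
            s += 1
            placements.add(s)
        expected = any(p < cut + 10 and p + 2 > cut - 10 for p in placements)
        assert got == expected, f"deletion at {start - cut:+d}"


def test_quantify_hand_enumerated_counts(locus):
    amplicon, guide, cut = locus
    reads = (
        [_del_at(amplicon, cut - 1, 1)] * 3
        + [_sub_at(amplicon, cut - 8)] * 2
        + [amplicon.sequence] * 5
    )
    a2 = quantify(reads, amplicon, guide, 2)
    a20 = quantify(reads, amplicon, guide, 20)
    assert (a2.n_modified, a2.n_unmodified) == (3, 7)
    assert a2.aee == pytest.approx(0.30)
    assert a20.aee == pytest.approx(0.50)
    assert a2.n_total == 10


def test_quantify_degenerate_read_sets(locus):
    amplicon, guide, cut = locus
    assert quantify([amplicon.sequence] * 5, amplicon, guide, 2).aee == 0.0
    edited = [_del_at(amplicon, cut - 1, 2)] * 5
    assert quantify(edited, amplicon, guide, 2).aee == 1.0
    assert quantify(edited, amplicon, guide, 20).aee == 1.0


def test_quantify_no_aligned_reads_errors(locus, rng):
    amplicon, guide, cut = locus
    junk = ["".join(rng.choice(list("ACGT"), size=len(amplicon))) for _ in range(3)]
    with pytest.raises(ValueError, match="no aligned reads"):
        quantify(junk, amplicon, guide, 2)


def test_allele_table_single_template(locus):
    amplicon, guide, cut = locus
    table = allele_table([amplicon.sequence] * 20, amplicon, guide)
    assert len(table.records) == 1
    assert table.records[0].frequency == 1.0
    assert not table.records[0].modified_in_window


def test_allele_table_two_templates(locus):
    amplicon, guide, cut = locus
    variant = _sub_at(amplicon, cut - 5)
    reads = [amplicon.sequence] * 74 + [variant] * 26
    table = allele_table(reads, amplicon, guide)
    assert [r.count for r in table.records] == [74, 26]
    assert table.records[1].frequency == pytest.approx(0.26)
    assert table.records[1].substitution_only


def test_allele_table_matches_seeded_multinomial(locus, rng):
    amplicon, guide, cut = locus
    templates = [amplicon.sequence, _sub_at(amplicon, cut - 5), _del_at(amplicon, cut - 1, 2)]
    draws = rng.multinomial(1000, [0.5, 0.3, 0.2])
    reads = [t for t, n in zip(templates, draws) for _ in range(n)]
    table = allele_table(reads, amplicon, guide)
    assert sorted(r.count for r in table.records) == sorted(draws)
    assert sum(r.count for r in table.records) == 1000
    assert sum(r.frequency for r in table.records) == pytest.approx(1.0, abs=1e-9)


def test_window_nesting_monotonicity_on_mixed_reads(locus, rng):
    """Any read modified in the 2-nt window is modified in the 20-nt window."""
    amplicon, guide, cut = locus
    reads = []
    for _ in range(50):
        pos = int(rng.integers(cut - 15, cut + 15))
        kind = rng.integers(3)
        if kind == 0:
            reads.append(_sub_at(amplicon, pos))
        elif kind == 1:
            reads.append(_del_at(amplicon, pos, int(rng.integers(1, 4))))
        else:
            reads.append(amplicon.sequence)
    a2 = quantify(reads, amplicon, guide, 2)
    a20 = quantify(reads, amplicon, guide, 20)
    assert a2.aee <= a20.aee + 1e-12
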