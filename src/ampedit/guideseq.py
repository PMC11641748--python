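"""Desk-scale GUIDE-seq-style integration-site detection and scoring.

dsODN-tagged reads reveal double-strand-break repair sites: a read is
tagged when the dsODN occurs in it (either orientation) within a mismatch
budget, the genomic flank 5' of the tag junction is mapped back to the
genome with an exact k-mer seed index plus Hamming verification, junctions
are clustered into integration sites, and each site is scored against the
guide by the best ungapped protospacer+PAM placement nearby.

No UMI consolidation is performed (the simulator emits unique molecules);
distinct-read counting stands in, which overstates counts on real
libraries with PCR duplicates.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .quant import GuideSpec, revcomp


@dataclass(frozen=True)
class DsodnSpec:
    """The double-stranded tag and the mismatch budget for finding it."""

    sequence: str
    max_mismatches: int = 1

    def __post_init__(self) -> None:
        if len(self.sequence) < 16:
            raise ValueError("dsODN must be at least 16 nt")


@dataclass
class TaggedRead:
    read_id: str
    flank: str  # genomic segment 5' of the tag junction, tag orientation normalised
    tag_orientation: str  # + if the tag matched as given, - if reverse complement


@dataclass
class Placement:
    contig: str
    start: int
    end: int
    strand: str
    mismatches: int

    @property
    def junction(self) -> int:
        """Genomic coordinate of the flank end abutting the tag."""
        return self.end if self.strand == "+" else self.start


@dataclass
class IntegrationSite:
    contig: str
    position: int  # 0-based inter-base junction
    strand: str
    read_count: int
    read_ids: list[str] = field(default_factory=list)
    flank_example: str = ""


@dataclass
class OfftargetRecord:
    site: IntegrationSite
    protospacer_match: str
    pam: str
    target_strand: str
    cut_position: int
    n_mismatches: int
    mismatch_positions: list[int]
    has_pam: bool
    is_on_target: bool
    read_fraction_of_total: float = 0.0


def _hamming_search(seq: str, pattern: str, max_mm: int) -> int:
    """Leftmost occurrence of pattern in seq with <= max_mm mismatches, else -1."""
    if max_mm == 0:
        return seq.find(pattern)
    hit = seq.find(pattern)  # exact fast path
    if hit >= 0:
        return hit
    m = len(pattern)
    if m > len(seq):
        return -1
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    p = np.frombuffer(pattern.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    mism = (windows != p).sum(axis=1)
    best = int(np.argmax(mism <= max_mm)) if np.any(mism <= max_mm) else -1
    return best


def find_dsodn_reads(
    reads: Iterable, dsodn: DsodnSpec, min_flank: int = 20
) -> list[TaggedRead]:
    """Extract the genomic flank upstream of the dsODN junction per read.

    Both tag orientations are searched; a read found with the tag in
    reverse-complement orientation is flipped so the flank always sits 5'
    of the tag.  Reads whose flank is shorter than ``min_flank`` are
    dropped (too little sequence to map confidently).
    """
    tagged: list[TaggedRead] = []
    tag_rc = revcomp(dsodn.sequence)
    for r in reads:
        rid, seq = (r.id, r.sequence) if hasattr(r, "sequence") else r
        seq = seq.upper()
        pos = _hamming_search(seq, dsodn.sequence, dsodn.max_mismatches)
        orientation = "+"
        if pos < 0:
            pos_rc = _hamming_search(seq, tag_rc, dsodn.max_mismatches)
            if pos_rc < 0:
                continue
            seq = revcomp(seq)
            pos = len(seq) - pos_rc - len(dsodn.sequence)
            orientation = "-"
        flank = seq[:pos]
        if len(flank) < min_flank:
            continue
        tagged.append(TaggedRead(rid, flank, orientation))
    return tagged


class GenomeIndex:
    """Exact k-mer seed index over a small genome, both strands via query RC."""

    def __init__(self, genome: dict[str, str], k: int = 12):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for contig, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                self._index[seq[i : i + k]].append((contig, i))

    def map_flank(self, flank: str, max_mismatches: int = 1) -> list[Placement]:
        """All placements of the flank with <= max_mismatches, both strands.

        Seeds are taken at ``max_mismatches + 1`` disjoint offsets
        (pigeonhole: at least one seed is exact), candidates verified by
        Hamming distance.  Equivalent to an exhaustive scan on small
        genomes, which the tests assert.
        """
        if not flank:
            raise ValueError("empty flank")
        flank = flank.upper()
        if len(flank) < self.k:
            raise ValueError(f"flank shorter than the seed size ({self.k})")
        hits: set[tuple[str, int, str]] = set()
        results: list[Placement] = []
        for strand, query in (("+", flank), ("-", revcomp(flank))):
            m = len(query)
            n_seeds = max_mismatches + 1
            offsets = {min(j * (m // n_seeds), m - self.k) for j in range(n_seeds)}
            for off in offsets:
                for contig, pos in self._index.get(query[off : off + self.k], ()):
                    start = pos - off
                    seq = self.genome[contig]
                    if start < 0 or start + m > len(seq):
                        continue
                    key = (contig, start, strand)
                    if key in hits:
                        continue
                    mm = sum(a != b for a, b in zip(seq[start : start + m], query))
                    if mm <= max_mismatches:
                        hits.add(key)
                        results.append(Placement(contig, start, start + m, strand, mm))
        results.sort(key=lambda p: (p.contig, p.start, p.strand))
        return results


def map_flank(flank: str, genome: dict[str, str], max_map_mismatches: int = 1, k: int = 12) -> list[Placement]:
    """Convenience wrapper building a fresh index; batch callers should reuse one."""
    return GenomeIndex(genome, k=k).map_flank(flank, max_map_mismatches)


def cluster_sites(
    tagged: Sequence[TaggedRead],
    index: GenomeIndex,
    max_map_mismatches: int = 1,
    merge_distance: int = 10,
    min_reads: int = 2,
) -> list[IntegrationSite]:
    """Map tagged reads and merge nearby junctions into integration sites.

    Each read contributes one placement (fewest mismatches, ties to the
    leftmost).  Junctions within ``merge_distance`` on the same contig
    merge; the site coordinate is the junction supported by most reads.
    Sites with fewer than ``min_reads`` distinct reads are dropped.
    """
    by_contig: dict[str, list[tuple[int, TaggedRead, Placement]]] = defaultdict(list)
    for tr in tagged:
        placements = index.map_flank(tr.flank, max_map_mismatches)
        if not placements:
            continue
        best = min(placements, key=lambda p: (p.mismatches, p.contig, p.start))
        by_contig[best.contig].append((best.junction, tr, best))

    sites: list[IntegrationSite] = []
    for contig, entries in sorted(by_contig.items()):
        entries.sort(key=lambda e: e[0])
        cluster: list[tuple[int, TaggedRead, Placement]] = []
        for entry in entries:
            if cluster and entry[0] - cluster[-1][0] > merge_distance:
                sites.extend(_finalize_cluster(contig, cluster, min_reads))
                cluster = []
            cluster.append(entry)
        if cluster:
            sites.extend(_finalize_cluster(contig, cluster, min_reads))
    sites.sort(key=lambda s: (-s.read_count, s.contig, s.position))
    return sites


def _finalize_cluster(contig: str, cluster, min_reads: int) -> list[IntegrationSite]:
    read_ids = sorted({tr.read_id for _, tr, _ in cluster})
    if len(read_ids) < min_reads:
        return []
    junctions = pd.Series([j for j, _, _ in cluster])
    position = int(junctions.mode().min())
    strand = pd.Series([p.strand for _, _, p in cluster]).mode()[0]
    flank_example = max((tr.flank for _, tr, _ in cluster), key=len)
    return [IntegrationSite(contig, position, strand, len(read_ids), read_ids, flank_example)]


def score_site_vs_guide(
    site: IntegrationSite,
    genome: dict[str, str],
    guide: GuideSpec,
    span: int = 25,
    on_target_position: int | None = None,
    position_tolerance: int = 10,
) -> OfftargetRecord:
    """Best ungapped protospacer+PAM placement within ``site +/- span``.

    Placements with an NGG PAM are preferred; among them the protospacer
    mismatch count is minimised, ties broken by cut-position distance to
    the junction.  If no NGG placement exists in the span, the best
    PAM-less match is reported and flagged.
    """
    seq = genome[site.contig]
    proto = guide.protospacer
    lo = max(0, site.position - span - 23)
    hi = min(len(seq) - 23, site.position + span)
    if hi < lo:
        raise ValueError("site too close to the contig edge for scoring")
    candidates = []  # (no_pam, mismatches, distance, start, strand, matched, pam, cut)
    for s in range(lo, hi + 1):
        window = seq[s : s + 23]
        # forward orientation: protospacer then NGG
        matched, pam = window[:20], window[20:]
        mm = [i for i in range(20) if matched[i] != proto[i]]
        cut = s + 17
        candidates.append((pam[1:] != "GG", len(mm), abs(cut - site.position), s, "+", matched, pam, cut, mm))
        # reverse orientation: rc(PAM) then rc(protospacer)
        matched_rc = revcomp(window[3:])
        pam_rc = revcomp(window[:3])
        mm_rc = [i for i in range(20) if matched_rc[i] != proto[i]]
        cut_rc = s + 3 + (20 - 17)
        candidates.append((pam_rc[1:] != "GG", len(mm_rc), abs(cut_rc - site.position), s, "-", matched_rc, pam_rc, cut_rc, mm_rc))
    no_pam, n_mm, _, _, strand, matched, pam, cut, mm_pos = min(candidates)
    is_on = (
        n_mm == 0
        and not no_pam
        and (on_target_position is None or abs(cut - on_target_position) <= position_tolerance)
    )
    return OfftargetRecord(
        site=site,
        protospacer_match=matched,
        pam=pam,
        target_strand=strand,
        cut_position=cut,
        n_mismatches=n_mm,
        mismatch_positions=mm_pos,
        has_pam=not no_pam,
        is_on_target=is_on,
    )


def offtarget_report(
    records: Sequence[OfftargetRecord],
    total_reads: int,
    tagged_reads: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-site table plus aggregate off-target read fractions.

    The off-target fraction is reported against the total read count and,
    when given, against tagged reads only -- the natural denominator is
    ambiguous, so both are emitted.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    rows = []
    for rec in sorted(records, key=lambda r: (not r.is_on_target, -r.site.read_count)):
        rec.read_fraction_of_total = rec.site.read_count / total_reads
        rows.append(
            {
                "contig": rec.site.contig,
                "position": rec.site.position,
                "strand": rec.target_strand,
                "read_count": rec.site.read_count,
                "protospacer_match": rec.protospacer_match,
                "pam": rec.pam,
                "n_mismatches": rec.n_mismatches,
                "mismatch_positions": ";".join(map(str, rec.mismatch_positions)),
                "has_pam": rec.has_pam,
                "is_on_target": rec.is_on_target,
                "read_fraction_of_total": rec.read_fraction_of_total,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "contig", "position", "strand", "read_count", "protospacer_match", "pam",
            "n_mismatches", "mismatch_positions", "has_pam", "is_on_target",
            "read_fraction_of_total",
        ],
    )
    off_reads = int(sum(r.site.read_count for r in records if not r.is_on_target))
    on_reads = int(sum(r.site.read_count for r in records if r.is_on_target))
    summary = {
        "n_sites": len(records),
        "n_on_target_sites": sum(r.is_on_target for r in records),
        "n_off_target_sites": sum(not r.is_on_target for r in records),
        "on_target_reads": on_reads,
        "off_target_reads": off_reads,
        "off_target_fraction_of_total": off_reads / total_reads,
        "off_target_fraction_of_tagged": (off_reads / tagged_reads) if tagged_reads else None,
    }
    return table, summary


def sites_to_bed(sites: Sequence[IntegrationSite]) -> str:
    """Render integration sites as BED (0-based half-open, junction +/- 1)."""
    lines = [
        f"{s.contig}\t{max(0, s.position - 1)}\t{s.position + 1}\tsite_{i}\t{s.read_count}\t{s.strand}"
        for i, s in enumerate(sorted(sites, key=lambda s: (s.contig, s.position)))
    ]
    return "\n".join(lines) + ("\n" if lines else "")
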