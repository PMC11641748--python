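"""Global pairwise alignment of amplicon reads with normalised event calls.

Reads are aligned end-to-end against the reference amplicon with an
affine-gap Needleman-Wunsch scheme (Biopython's ``PairwiseAligner`` does the
dynamic programming).  The alignment path is then decomposed into atomic
modification events -- per-base substitutions, maximal deletion runs, and
insertion runs anchored at inter-base coordinates -- and every indel is
shifted to its leftmost score-equivalent placement so that downstream
window-overlap tests are deterministic regardless of how the aligner broke
ties.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Sequence

from Bio import Align

DNA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring scheme.

    A gap of length L costs ``gap_open + L * gap_extend``.  Reads whose
    identity (matches / alignment columns) falls below ``min_identity``
    are discarded rather than classified.
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -6.0
    gap_extend: float = -1.0
    min_identity: float = 0.6


@dataclass(frozen=True)
class ModificationEvent:
    """A single difference between read and reference.

    ``ref_start`` is 0-based; for insertions it is the inter-base anchor
    (the insertion sits between ``ref_start - 1`` and ``ref_start``) and
    ``ref_length`` is 0.  ``alt`` holds inserted or substituted bases.
    """

    kind: str  # insertion | deletion | substitution
    ref_start: int
    ref_length: int
    alt: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion", "substitution"):
            raise ValueError(f"unknown event kind: {self.kind!r}")


@dataclass
class ReadAlignment:
    """Outcome of aligning one read against the amplicon."""

    read: str
    score: float
    identity: float
    events: list[ModificationEvent]
    discarded: bool = False


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-DNA characters: {sorted(bad)}")
    return seq


@lru_cache(maxsize=8)
def _aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # Biopython charges open_gap_score for the first gap column and
    # extend_gap_score for each subsequent one; our convention charges
    # open + extend already at length 1.
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def left_normalize(events: Sequence[ModificationEvent], ref: str) -> list[ModificationEvent]:
    """Shift indels to their leftmost sequence-equivalent placement.

    A deletion of ``ref[s:s+L]`` may slide left one step whenever
    ``ref[s-1] == ref[s+L-1]``; an insertion slides left by rotating its
    inserted bases.  Substitutions are untouched.
    """
    out: list[ModificationEvent] = []
    for ev in events:
        if ev.kind == "deletion":
            s, length = ev.ref_start, ev.ref_length
            while s > 0 and ref[s - 1] == ref[s + length - 1]:
                s -= 1
            out.append(replace(ev, ref_start=s))
        elif ev.kind == "insertion":
            anchor, ins = ev.ref_start, ev.alt
            while anchor > 0 and ins and ref[anchor - 1] == ins[-1]:
                ins = ins[-1] + ins[:-1]
                anchor -= 1
            out.append(replace(ev, ref_start=anchor, alt=ins))
        else:
            out.append(ev)
    out.sort(key=lambda e: (e.ref_start, e.kind))
    return out


def _events_from_path(ref: str, read: str, coordinates) -> tuple[list[ModificationEvent], float]:
    """Decompose an alignment path into events and compute identity."""
    events: list[ModificationEvent] = []
    matches = 0
    columns = 0
    ncols = coordinates.shape[1]
    for i in range(ncols - 1):
        t0, t1 = int(coordinates[0, i]), int(coordinates[0, i + 1])
        q0, q1 = int(coordinates[1, i]), int(coordinates[1, i + 1])
        if t1 > t0 and q1 > q0:  # aligned block
            for j in range(t1 - t0):
                a, b = ref[t0 + j], read[q0 + j]
                if a == b:
                    matches += 1
                else:
                    events.append(ModificationEvent("substitution", t0 + j, 1, b))
            columns += t1 - t0
        elif t1 > t0:  # gap in the read: deletion from the reference
            events.append(ModificationEvent("deletion", t0, t1 - t0))
            columns += t1 - t0
        else:  # gap in the reference: insertion
            events.append(ModificationEvent("insertion", t0, 0, read[q0:q1]))
            columns += q1 - q0
    identity = matches / columns if columns else 0.0
    return events, identity


def align_read(read: str, reference: str, scoring: Scoring | None = None) -> ReadAlignment:
    """Globally align one read to the reference amplicon.

    Returns a :class:`ReadAlignment` with left-normalised events; reads
    whose identity falls below ``scoring.min_identity`` are flagged
    ``discarded`` (their events are still reported for diagnostics).
    """
    scoring = scoring or Scoring()
    read = _check_dna(read, "read")
    reference = _check_dna(reference, "reference")
    if not read:
        raise ValueError("empty read")
    aln = _aligner(scoring).align(reference, read)[0]
    events, identity = _events_from_path(reference, read, aln.coordinates)
    events = left_normalize(events, reference)
    return ReadAlignment(
        read=read,
        score=float(aln.score),
        identity=identity,
        events=events,
        discarded=identity < scoring.min_identity,
    )


@dataclass
class AlignedRead:
    """A distinct read sequence with its multiplicity and alignment."""

    sequence: str
    count: int
    alignment: ReadAlignment


def align_readset(reads: Iterable[str], reference: str, scoring: Scoring | None = None) -> list[AlignedRead]:
    """Align a read set, collapsing identical sequences first.

    Amplicon data is massively redundant (most reads are exact copies of a
    few templates), so deduplication is both the natural unit for allele
    tables and the main performance lever.
    """
    scoring = scoring or Scoring()
    counts = Counter(r.upper() for r in reads)
    return [
        AlignedRead(seq, n, align_read(seq, reference, scoring))
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
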