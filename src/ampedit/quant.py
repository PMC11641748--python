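"""Quantification of editing inside cut-site-centred windows.

The central statistic is the alleged editing efficiency (AEE): the fraction
of aligned reads that carry any insertion, deletion or substitution inside a
quantification window of width *w* nucleotides centred on the predicted Cas9
cut site.  "Alleged" because pre-existing genetic variation inside the
window is indistinguishable from editing at this stage -- separating the two
is the job of the control-based classifier.

Coordinates are 0-based and half-open throughout; the cut site is an
inter-base coordinate (the canonical SpCas9 blunt cut, 3 bp 5' of the PAM,
i.e. 17 nt from the protospacer 5' end).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .align import (
    AlignedRead,
    ModificationEvent,
    ReadAlignment,
    Scoring,
    _check_dna,
    align_readset,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Amplicon:
    """A reference amplicon sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_dna(self.sequence, "amplicon"))
        if len(self.sequence) < 80:
            raise ValueError(f"amplicon {self.id!r} shorter than 80 nt ({len(self.sequence)})")

    def __len__(self) -> int:
        return len(self.sequence)


_PAM_RE = re.compile("[ACGTN]GG")


@dataclass(frozen=True)
class GuideSpec:
    """An sgRNA target annotated on an amplicon.

    ``protospacer_start`` is the 0-based coordinate, on the amplicon's
    forward strand, of the 20-nt protospacer footprint.  On the minus
    strand the footprint holds the reverse complement of the protospacer
    and the (reverse-complemented) PAM lies immediately 5' of it on the
    forward strand.  ``cut_offset`` is measured from the protospacer 5'
    end; the SpCas9 blunt cut sits at 17.
    """

    protospacer: str
    pam: str = "NGG"
    strand: str = "+"
    protospacer_start: int = 0
    cut_offset: int = 17

    def __post_init__(self) -> None:
        object.__setattr__(self, "protospacer", _check_dna(self.protospacer, "protospacer"))
        object.__setattr__(self, "pam", _check_dna(self.pam, "pam"))
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be 20 nt")
        if not _PAM_RE.fullmatch(self.pam):
            raise ValueError(f"PAM {self.pam!r} does not match NGG")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not 0 < self.cut_offset < 20:
            raise ValueError("cut_offset must lie strictly inside the protospacer")

    def validate_against(self, amplicon: Amplicon) -> None:
        """Require an exact protospacer+PAM match at the stated position."""
        seq = amplicon.sequence
        ps, length = self.protospacer_start, len(self.protospacer)
        if self.strand == "+":
            found = seq[ps : ps + length]
            pam_found = seq[ps + length : ps + length + 3]
        else:
            found = revcomp(seq[ps : ps + length])
            pam_found = revcomp(seq[ps - 3 : ps])
        if found != self.protospacer:
            raise ValueError(
                f"protospacer mismatch at {self.protospacer_start} ({self.strand}): "
                f"expected {self.protospacer}, amplicon has {found or '(out of bounds)'}"
            )
        if len(pam_found) != 3 or pam_found[1:] != "GG":
            raise ValueError(f"no NGG PAM adjacent to protospacer (found {pam_found!r})")


def cut_site(guide: GuideSpec, amplicon: Amplicon) -> int:
    """Inter-base cut coordinate on the amplicon forward strand.

    For a plus-strand guide the cut falls ``cut_offset`` nt into the
    protospacer; on the minus strand the arithmetic mirrors.
    """
    guide.validate_against(amplicon)
    if guide.strand == "+":
        return guide.protospacer_start + guide.cut_offset
    return guide.protospacer_start + (len(guide.protospacer) - guide.cut_offset)


@dataclass(frozen=True)
class QuantWindow:
    """Half-open interval of width ``width`` centred on the cut site."""

    cut_site: int
    width: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.width % 2:
            raise ValueError("window width must be a positive even integer")

    def bounds(self, amplicon_length: int) -> tuple[int, int]:
        half = self.width // 2
        return max(0, self.cut_site - half), min(amplicon_length, self.cut_site + half)


@dataclass
class ModificationCall:
    """Whether an aligned read counts as modified inside a window."""

    modified: bool
    events_in_window: list[ModificationEvent]


def _event_in_window(ev: ModificationEvent, start: int, end: int, reference: str) -> bool:
    """Window test; indels are judged by their placement-equivalence range.

    Indel placement inside a repeated context is intrinsically ambiguous:
    the same read sequence admits several score-equivalent positions.
    Events are *reported* at their leftmost placement, but counting only
    that placement would let a cut-site deletion slide out of the narrow
    window whenever the cut lands in a homopolymer, biasing AEE downward.
    So an indel counts as in-window when any equivalent placement
    (leftmost through rightmost) touches the window.
    """
    if ev.kind == "substitution":
        # N on either side is ambiguity, not modification
        if ev.alt == "N" or reference[ev.ref_start] == "N":
            return False
        return start <= ev.ref_start < end
    if ev.kind == "deletion":
        s, length = ev.ref_start, ev.ref_length
        s_max = s
        while s_max + length < len(reference) and reference[s_max] == reference[s_max + length]:
            s_max += 1
        return s < end and s_max + length > start
    # insertion: counts when some equivalent anchor lies strictly inside
    a, a_max, rot = ev.ref_start, ev.ref_start, ev.alt
    while rot and a_max < len(reference) and rot[0] == reference[a_max]:
        a_max += 1
        rot = rot[1:] + rot[0]
    return a < end and a_max > start


def classify_read(alignment: ReadAlignment, window: QuantWindow, amplicon: Amplicon) -> ModificationCall:
    """Call a read modified iff any event touches the quantification window.

    Insertions count when anchored strictly inside the window, deletions
    when their reference interval overlaps it, substitutions when their
    position lies inside it.  Events outside the window never set the flag.
    """
    if alignment.discarded:
        raise ValueError("cannot classify a discarded alignment")
    start, end = window.bounds(len(amplicon))
    hits = [ev for ev in alignment.events if _event_in_window(ev, start, end, amplicon.sequence)]
    return ModificationCall(modified=bool(hits), events_in_window=hits)


@dataclass
class AEEResult:
    """Modified/unmodified tally and the resulting AEE for one window."""

    n_modified: int
    n_unmodified: int
    n_discarded: int
    window: QuantWindow

    @property
    def aee(self) -> float:
        return self.n_modified / (self.n_modified + self.n_unmodified)

    @property
    def n_total(self) -> int:
        return self.n_modified + self.n_unmodified + self.n_discarded


def _as_sequences(reads: Iterable) -> list[str]:
    out = []
    for r in reads:
        out.append(r if isinstance(r, str) else r.sequence)
    return out


def quantify(
    reads: Iterable,
    amplicon: Amplicon,
    guide: GuideSpec,
    width: int,
    scoring: Scoring | None = None,
    aligned: Sequence[AlignedRead] | None = None,
) -> AEEResult:
    """Compute the AEE of a read set for one window width.

    ``aligned`` may carry a pre-computed :func:`align_readset` result so
    that multiple windows (and the allele table) share one alignment pass.
    """
    if width < 2 or width % 2:
        raise ValueError("width must be an even integer >= 2")
    site = cut_site(guide, amplicon)
    window = QuantWindow(site, width)
    if aligned is None:
        aligned = align_readset(_as_sequences(reads), amplicon.sequence, scoring)
    n_mod = n_unmod = n_disc = 0
    for ar in aligned:
        if ar.alignment.discarded:
            n_disc += ar.count
            continue
        call = classify_read(ar.alignment, window, amplicon)
        if call.modified:
            n_mod += ar.count
        else:
            n_unmod += ar.count
    if n_mod + n_unmod == 0:
        raise ValueError("no aligned reads")
    return AEEResult(n_mod, n_unmod, n_disc, window)


# ---------------------------------------------------------------------------
# Allele tables


@dataclass
class AlleleRecord:
    """A collapsed read variant over the report span around the cut site."""

    aligned_sequence: str
    count: int
    frequency: float
    events: list[ModificationEvent]
    modified_w2: bool
    modified_w20: bool

    @property
    def modified_in_window(self) -> bool:
        return self.modified_w20

    @property
    def substitution_only(self) -> bool:
        return bool(self.events) and all(ev.kind == "substitution" for ev in self.events)

    @property
    def has_indel(self) -> bool:
        return any(ev.kind in ("insertion", "deletion") for ev in self.events)


@dataclass
class AlleleTable:
    """Fig-style allele frequency table for one sample."""

    records: list[AlleleRecord]
    span: tuple[int, int]
    cut_site: int
    n_aligned: int
    n_discarded: int


def _render_span(reference: str, events: Sequence[ModificationEvent], start: int, end: int) -> str:
    """Render the read as aligned text over ``[start, end)`` of the reference.

    Deleted positions show ``-``; insertions anchored strictly inside the
    span appear as lowercase runs in parentheses before their anchor.
    """
    deleted: set[int] = set()
    subs: dict[int, str] = {}
    inserts: dict[int, str] = {}
    for ev in events:
        if ev.kind == "deletion":
            deleted.update(range(ev.ref_start, ev.ref_start + ev.ref_length))
        elif ev.kind == "substitution":
            subs[ev.ref_start] = ev.alt
        elif start < ev.ref_start < end:
            inserts[ev.ref_start] = inserts.get(ev.ref_start, "") + ev.alt
    parts: list[str] = []
    for p in range(start, end):
        if p in inserts:
            parts.append(f"(+{inserts[p].lower()})")
        if p in deleted:
            parts.append("-")
        else:
            parts.append(subs.get(p, reference[p]))
    return "".join(parts)


def _events_in_span(events: Sequence[ModificationEvent], start: int, end: int) -> list[ModificationEvent]:
    keep = []
    for ev in events:
        if ev.kind == "deletion":
            if ev.ref_start < end and ev.ref_start + ev.ref_length > start:
                keep.append(ev)
        elif ev.kind == "substitution":
            if start <= ev.ref_start < end:
                keep.append(ev)
        elif start < ev.ref_start < end:
            keep.append(ev)
    return keep


def allele_table(
    reads: Iterable,
    amplicon: Amplicon,
    guide: GuideSpec,
    report_span: int = 40,
    scoring: Scoring | None = None,
    aligned: Sequence[AlignedRead] | None = None,
) -> AlleleTable:
    """Collapse aligned reads into allele records over a cut-centred span.

    Reads are grouped by their rendered aligned sequence over the span
    (default +/-20 nt); frequencies are relative to aligned reads and sum
    to one.  Records are ordered by count descending, then lexicographic.
    """
    if report_span <= 0 or report_span % 2:
        raise ValueError("report_span must be a positive even integer")
    site = cut_site(guide, amplicon)
    start = max(0, site - report_span // 2)
    end = min(len(amplicon), site + report_span // 2)
    if aligned is None:
        aligned = align_readset(_as_sequences(reads), amplicon.sequence, scoring)
    w2 = QuantWindow(site, 2)
    w20 = QuantWindow(site, 20)

    groups: dict[str, dict] = {}
    n_aligned = n_disc = 0
    for ar in aligned:
        if ar.alignment.discarded:
            n_disc += ar.count
            continue
        n_aligned += ar.count
        key = _render_span(amplicon.sequence, ar.alignment.events, start, end)
        g = groups.setdefault(key, {"count": 0, "events": None, "m2": False, "m20": False})
        g["count"] += ar.count
        if g["events"] is None:
            g["events"] = _events_in_span(ar.alignment.events, start, end)
            g["m2"] = classify_read(ar.alignment, w2, amplicon).modified
            g["m20"] = classify_read(ar.alignment, w20, amplicon).modified
    if n_aligned == 0:
        raise ValueError("no aligned reads")
    records = [
        AlleleRecord(
            aligned_sequence=key,
            count=g["count"],
            frequency=g["count"] / n_aligned,
            events=g["events"],
            modified_w2=g["m2"],
            modified_w20=g["m20"],
        )
        for key, g in groups.items()
    ]
    records.sort(key=lambda r: (-r.count, r.aligned_sequence))
    return AlleleTable(records, (start, end), site, n_aligned, n_disc)


def render_allele_table(table: AlleleTable, amplicon: Amplicon, max_rows: int = 15) -> str:
    """Plain-text rendering: reference on top, alleles with frequencies below."""
    start, end = table.span
    lines = [f"{amplicon.sequence[start:end]}   reference  (cut at {table.cut_site})"]
    for rec in table.records[:max_rows]:
        flag = "*" if rec.modified_in_window else " "
        lines.append(f"{rec.aligned_sequence}  {flag} {100 * rec.frequency:6.2f}%  n={rec.count}")
    if len(table.records) > max_rows:
        lines.append(f"... {len(table.records) - max_rows} more alleles")
    return "\n".join(lines)
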