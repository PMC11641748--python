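"""FASTA/FASTQ/TSV serialisation helpers (Biopython-backed).

All coordinates in truth/site files are 0-based half-open.  FASTQ quality
is a fixed 'I' (Q40): the simulator has no quality model and the analysis
uses sequence identity only.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import SimRead


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    try:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    except Exception as exc:  # pragma: no cover - Biopython error text varies
        raise ValueError(f"malformed FASTA {path}: {exc}") from exc
    if not records:
        raise ValueError(f"no sequences found in FASTA {path}")
    return records


def write_fastq(reads: Iterable[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def read_fastq(path: str | Path) -> list[SimRead]:
    reads = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            reads.append(SimRead(rec.id, str(rec.seq).upper()))
    except Exception as exc:
        raise ValueError(f"malformed FASTQ {path}: {exc}") from exc
    if not reads:
        raise ValueError(f"no reads found in FASTQ {path}")
    return reads
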