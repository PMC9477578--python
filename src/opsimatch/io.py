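"""Readers and writers for the formats the tool touches.

FASTA reading/writing goes through Biopython; hits are serialized as TSV
(with header) or BED (3+2 columns).  All coordinates are 0-based, half-open
``[start, end)`` — matching BED and this package's index arithmetic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exact import Sequence
from .sbarc import InvalidInputError


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class HitRecord:
    """A serializable occurrence on a named record: half-open interval
    ``[start, end)`` with its mismatch count (0 for exact hits)."""

    record_id: str
    start: int
    end: int
    mismatch_count: int = 0
    mismatch_offsets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise InvalidInputError(f"invalid interval [{self.start}, {self.end})")


def read_sequences(path: str | Path, format: str = "fasta") -> list[Sequence]:
    """Read sequences from FASTA (multi-record) or raw text (one sequence,
    whitespace stripped).  Residues are uppercased; FASTA ids are preserved,
    a raw file is named after its basename."""
    path = Path(path)
    if format == "raw":
        text = path.read_text()
        residues = "".join(text.split())
        if not residues:
            raise ParseError(f"{path}: empty sequence file")
        return [Sequence(path.stem, residues)]
    if format != "fasta":
        raise InvalidInputError(f"unknown sequence format {format!r}")
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ParseError(f"{path}:{lineno}: sequence data before the first FASTA header")
            break
        else:
            raise ParseError(f"{path}: empty FASTA file")
    records = [
        Sequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(os.fspath(path), "fasta")
    ]
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: Iterable[Sequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.identifier, description="") for s in sequences
    ]
    SeqIO.write(records, os.fspath(path), "fasta")


TSV_HEADER = ("record_id", "start", "end", "mismatches", "offsets")


def _ordered(hits: Iterable[HitRecord]) -> list[HitRecord]:
    hits = list(hits)
    first_seen: dict[str, int] = {}
    for h in hits:
        first_seen.setdefault(h.record_id, len(first_seen))
    return sorted(hits, key=lambda h: (first_seen[h.record_id], h.start))


def format_hits(hits: Iterable[HitRecord], format: str = "tsv", one_based: bool = False) -> str:
    """Render hits as TSV (with header) or BED3+2 text.

    ``one_based`` shifts the displayed TSV interval to 1-based inclusive;
    BED output is always 0-based half-open as the format requires.
    """
    rows = _ordered(hits)
    if format == "tsv":
        shift = 1 if one_based else 0
        lines = ["\t".join(TSV_HEADER)]
        for h in rows:
            offsets = ",".join(str(o) for o in h.mismatch_offsets)
            lines.append(f"{h.record_id}\t{h.start + shift}\t{h.end}\t{h.mismatch_count}\t{offsets}")
        return "\n".join(lines) + "\n"
    if format == "bed":
        return "".join(
            f"{h.record_id}\t{h.start}\t{h.end}\t.\t{h.mismatch_count}\n" for h in rows
        )
    raise InvalidInputError(f"unknown hit format {format!r}")


def write_hits(
    hits: Iterable[HitRecord], path: str | Path, format: str = "tsv", one_based: bool = False
) -> None:
    Path(path).write_text(format_hits(hits, format, one_based))


def read_hits_tsv(path: str | Path) -> list[HitRecord]:
    """Parse a TSV hit file written by :func:`write_hits` (0-based output)."""
    lines = Path(path).read_text().splitlines()
    if not lines or tuple(lines[0].split("\t")) != TSV_HEADER:
        raise ParseError(f"{path}: missing or malformed TSV header")
    hits = []
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 tab-separated fields")
        rec, start, end, mm, offsets = fields
        parsed = tuple(int(o) for o in offsets.split(",")) if offsets else ()
        hits.append(HitRecord(rec, int(start), int(end), int(mm), parsed))
    return hits
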