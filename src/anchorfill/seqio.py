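"""Sequence and interval I/O.

All coordinates exchanged between modules are 0-based half-open.
FASTA records are uppercased on read and any IUPAC ambiguity code
outside {A,C,G,T,N} is converted to N with a warning, so that every
downstream alphabet (k-mers, alignment, satellite scanning) is closed.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

from Bio import SeqIO

logger = logging.getLogger("anchorfill")

_VALID = set("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the closed alphabet {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Sequence:
    """A named DNA sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a named sequence.

    ``strand`` is '+', '-' or '.' (unstranded).
    """

    seq_id: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: str = "."

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:
        return self.end - self.start


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[Sequence]:
    """Read a (possibly gzipped) FASTA file.

    Records are uppercased; non-ACGTN characters become N (warned).
    Duplicate ids and empty records are hard errors.
    """
    records: list[Sequence] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id: {rec.id}")
            seen.add(rec.id)
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"empty FASTA record: {rec.id}")
            n_bad = len(_NON_ACGTN.findall(seq))
            if n_bad:
                logger.warning(
                    "%s: %d non-ACGTN character(s) converted to N", rec.id, n_bad
                )
                seq = _NON_ACGTN.sub("N", seq)
            records.append(Sequence(rec.id, seq))
    return records


def write_fasta(sequences: Iterable[Sequence], path, width: int = 80) -> None:
    """Write FASTA with fixed 80-column wrapping (deterministic diffs)."""
    with _open_text(path, "wt") as fh:
        for s in sequences:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i : i + width] + "\n")


def sequences_to_dict(sequences: Iterable[Sequence]) -> dict[str, Sequence]:
    out: dict[str, Sequence] = {}
    for s in sequences:
        if s.id in out:
            raise ValueError(f"duplicate sequence id: {s.id}")
        out[s.id] = s
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write 6-column BED (0-based half-open)."""
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score}\t{iv.strand}\n"
            )


def read_bed(path) -> list[GenomicInterval]:
    """Read BED (3 to 6 columns); malformed lines error with line number."""
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 else "."
            score = fields[4] if len(fields) > 4 else "."
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in {"+", "-", "."}:
                raise ValueError(f"{path}: line {lineno}: bad strand {strand!r}")
            try:
                out.append(GenomicInterval(fields[0], start, end, strand, name, score))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_CIGAR_OPS = set("M=XIDSH")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Parse a CIGAR string into (op, count) pairs.

    Accepted ops: M, =, X, I, D, S, H. Counts are positive integers and
    the concatenation of the pairs reproduces the input.
    """
    if not cigar:
        raise ValueError("empty CIGAR")
    out: list[tuple[str, int]] = []
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR at offset {pos}: {cigar!r}")
        count, op = int(m.group(1)), m.group(2)
        if op not in _CIGAR_OPS:
            raise ValueError(f"unsupported CIGAR op {op!r} in {cigar!r}")
        if count <= 0:
            raise ValueError(f"non-positive CIGAR count in {cigar!r}")
        out.append((op, count))
        pos = m.end()
    if pos != len(cigar):
        raise ValueError(f"malformed CIGAR at offset {pos}: {cigar!r}")
    return out


def cigar_to_string(pairs: TypingSequence[tuple[str, int]]) -> str:
    return "".join(f"{c}{op}" for op, c in pairs)
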