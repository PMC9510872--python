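"""Telomere-array detection and novel-region extraction.

Telomeres are detected as arrays of the plant telomeric unit
(CCCTAAA at 5' ends, its reverse complement TTTAGGG at 3' ends)
using a two-state scan that tolerates the degenerate unit copies real
telomeres carry, as long as array purity stays above a floor.

Novel regions are the complement of merged alignment coverage over
each target sequence: covered and novel intervals partition the
sequence exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .seqio import GenomicInterval, Sequence, reverse_complement

TELOMERE_UNIT = "CCCTAAA"


@dataclass(frozen=True)
class TelomereRecord:
    seq_id: str
    end: str  # "5'" | "3'"
    array_interval: GenomicInterval
    repeat_unit_count: int
    purity: float

    @property
    def length(self) -> int:
        return self.array_interval.length


def _scan_array(seq: str, unit: str, min_purity: float) -> tuple[int, int, float]:
    """Greedy left-anchored array scan.

    Starting at position 0, exact unit copies extend the array; a
    non-matching window advances by one base and counts as impurity.
    The array ends at the furthest extent where overall purity (bases
    inside exact copies / array length) stays >= min_purity.
    Returns (array_end, unit_count, purity) for the best extent.
    """
    u = len(unit)
    pos = 0
    pure = 0
    units = 0
    best = (0, 0, 1.0)
    while pos + u <= len(seq):
        if seq[pos : pos + u] == unit:
            pos += u
            pure += u
            units += 1
            purity = pure / pos
            if purity >= min_purity and pos > best[0]:
                best = (pos, units, purity)
        else:
            pos += 1
            if pos and pure / pos < min_purity * 0.5:
                break  # drifted far out of the array
    return best


def find_telomeres(
    assembly: Iterable[Sequence],
    unit: str = TELOMERE_UNIT,
    max_offset: int = 1000,
    min_units: int = 10,
    min_purity: float = 0.8,
) -> list[TelomereRecord]:
    """Telomeric arrays at sequence ends.

    The unit is searched at 5' ends and its reverse complement at 3'
    ends; the array must begin within ``max_offset`` of the end and
    contain at least ``min_units`` exact copies at purity
    >= ``min_purity``.
    """
    if len(unit) < 3:
        raise ValueError("unit too short")
    rc_unit = reverse_complement(unit)
    records: list[TelomereRecord] = []
    for seq in assembly:
        # 5' end: scan forward for `unit`
        start = seq.seq.find(unit, 0, max_offset + len(unit))
        if start != -1:
            end_pos, units, purity = _scan_array(seq.seq[start:], unit, min_purity)
            if units >= min_units:
                records.append(
                    TelomereRecord(
                        seq.id,
                        "5'",
                        GenomicInterval(seq.id, start, start + end_pos, "+"),
                        units,
                        purity,
                    )
                )
        # 3' end: scan the reverse complement's 5' end
        rc = reverse_complement(seq.seq)
        start = rc.find(unit, 0, max_offset + len(unit))
        if start != -1:
            end_pos, units, purity = _scan_array(rc[start:], unit, min_purity)
            if units >= min_units:
                L = len(seq.seq)
                records.append(
                    TelomereRecord(
                        seq.id,
                        "3'",
                        GenomicInterval(seq.id, L - start - end_pos, L - start, "-"),
                        units,
                        purity,
                    )
                )
    return records


def merge_intervals(intervals: Iterable[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_seq.setdefault(iv.seq_id, []).append((iv.start, iv.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for sid, ivs in by_seq.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[sid] = out
    return merged


def novel_regions(
    target_assembly: Iterable[Sequence],
    alignment_intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Complement of merged alignment coverage on each target sequence.

    Covered and novel intervals are disjoint and together partition
    every sequence. Identity/length filtering of the alignments is the
    caller's responsibility (defaults upstream: identity >= 0.95,
    length >= 10 kb).
    """
    covered = merge_intervals(alignment_intervals)
    novel: list[GenomicInterval] = []
    for seq in target_assembly:
        pos = 0
        for s, e in covered.get(seq.id, []):
            s, e = max(0, s), min(len(seq.seq), e)
            if s > pos:
                novel.append(GenomicInterval(seq.id, pos, s))
            pos = max(pos, e)
        if pos < len(seq.seq):
            novel.append(GenomicInterval(seq.id, pos, len(seq.seq)))
    return novel


def telomeres_tsv(records: list[TelomereRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq\tend\tstart\tstop\tunits\tlength\tpurity\n")
        for r in records:
            fh.write(
                f"{r.seq_id}\t{r.end}\t{r.array_interval.start}\t{r.array_interval.end}\t"
                f"{r.repeat_unit_count}\t{r.length}\t{r.purity:.4f}\n"
            )
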