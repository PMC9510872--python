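"""k-mer consensus quality (QV), accuracy and completeness.

The estimator follows the standard k-mer survey logic: every assembly
k-mer absent from the read set is treated as evidence of a consensus
error. With T total assembly k-mer instances and B of them unsupported
by reads, the per-base error probability is

    E = 1 - (1 - B/T)^(1/k)

(a base error corrupts up to k overlapping k-mers), the quality value
is QV = -10*log10(E), and

    accuracy% = 100 - 10^(QV/-10) * 100.

Completeness is the share of reliable read k-mers (multiplicity >=
a reliability floor, default 2) that appear in the assembly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping

import numpy as np

from .seqio import Sequence

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i

DEFAULT_K = 21
QV_CAP = 99.0


@dataclass(frozen=True)
class QVReport:
    """k-mer consensus-quality summary of one assembly."""

    k: int
    total_kmers: int          # T: assembly k-mer instances
    assembly_only_kmers: int  # B: instances unsupported by reads
    error_rate: float         # E
    qv: float
    accuracy_pct: float
    completeness_pct: float | None = None
    qv_capped: bool = False


def _encode_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical integer codes of all N-free k-mers of one sequence."""
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if len(codes) < k:
        return np.empty(0, dtype=np.uint64)
    valid = codes != 255
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    win = win[ok].astype(np.uint64)
    if win.size == 0:
        return np.empty(0, dtype=np.uint64)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    fwd = win @ powers
    rc_win = (np.uint64(3) - win)[:, ::-1]
    rev = rc_win @ powers
    return np.minimum(fwd, rev)


def count_kmers(sequences: Iterable[Sequence], k: int = DEFAULT_K) -> dict[int, int]:
    """Canonical k-mer multiset of a sequence collection.

    k must be odd (so no k-mer equals its own reverse complement) and
    at most 31 (codes fit in 64 bits). k-mers containing N are skipped.
    Returns a mapping canonical-code -> count.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd (canonicalization ambiguity)")
    if not 1 < k <= 31:
        raise ValueError("k must satisfy 1 < k <= 31")
    chunks = [_encode_kmers(s.seq, k) for s in sequences]
    chunks = [c for c in chunks if c.size]
    if not chunks:
        return {}
    codes, counts = np.unique(np.concatenate(chunks), return_counts=True)
    return dict(zip(codes.tolist(), counts.tolist()))


def kmer_code(kmer: str) -> int:
    """Canonical code of a single k-mer string (for TSV interchange)."""
    arr = _encode_kmers(kmer, len(kmer))
    if arr.size != 1:
        raise ValueError(f"not a clean k-mer: {kmer!r}")
    return int(arr[0])


def qv_to_accuracy(qv: float) -> float:
    """accuracy% = 100 - 10^(QV/-10) * 100, reported at 6 decimals."""
    if qv < 0:
        raise ValueError("qv must be non-negative")
    acc = 100.0 - (10.0 ** (qv / -10.0)) * 100.0
    return float(Decimal(repr(acc)).quantize(Decimal("0.000001"), ROUND_HALF_UP))


def estimate_qv(
    assembly_kmers: Mapping[int, int],
    read_kmers: Mapping[int, int],
    k: int,
    qv_cap: float = QV_CAP,
) -> QVReport:
    """QV of an assembly from its k-mer multiset versus a read k-mer set."""
    if not read_kmers:
        raise ValueError("read k-mer set is empty (uninformative)")
    total = sum(assembly_kmers.values())
    if total == 0:
        raise ValueError("assembly has no k-mers")
    only = sum(c for code, c in assembly_kmers.items() if code not in read_kmers)
    if only == 0:
        return QVReport(
            k=k,
            total_kmers=total,
            assembly_only_kmers=0,
            error_rate=0.0,
            qv=qv_cap,
            accuracy_pct=qv_to_accuracy(qv_cap),
            qv_capped=True,
        )
    err = 1.0 - (1.0 - only / total) ** (1.0 / k)
    qv = -10.0 * math.log10(err)
    return QVReport(
        k=k,
        total_kmers=total,
        assembly_only_kmers=only,
        error_rate=err,
        qv=qv,
        accuracy_pct=qv_to_accuracy(qv),
    )


def kmer_completeness(
    read_kmers: Mapping[int, int],
    assembly_kmers: Mapping[int, int],
    reliability_floor: int = 2,
) -> float:
    """Percent of reliable read k-mers present in the assembly.

    Read k-mers with multiplicity below the floor are treated as
    sequencing errors and excluded from the denominator.
    """
    if reliability_floor < 1:
        raise ValueError("reliability_floor must be >= 1")
    reliable = [code for code, c in read_kmers.items() if c >= reliability_floor]
    if not reliable:
        raise ValueError("no reliable read k-mers at this floor")
    found = sum(1 for code in reliable if code in assembly_kmers)
    return 100.0 * found / len(reliable)


def qv_report_tsv(report: QVReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("k\tT\tB\terror_rate\tqv\taccuracy_pct\tcompleteness_pct\tqv_capped\n")
        comp = "" if report.completeness_pct is None else f"{report.completeness_pct:.4f}"
        fh.write(
            f"{report.k}\t{report.total_kmers}\t{report.assembly_only_kmers}\t"
            f"{report.error_rate:.3e}\t{report.qv:.2f}\t{report.accuracy_pct:.6f}\t"
            f"{comp}\t{report.qv_capped}\n"
        )
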