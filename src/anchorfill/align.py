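"""Pairwise local alignment shared by anchoring, clone validation and
monomer detection.

The aligner is seed-and-extend: exact k-mer seeds (default k=15) are
clustered by diagonal, each cluster defines a candidate target window,
and the query is aligned into the window with edlib (infix mode, full
CIGAR). The infix alignment is then trimmed to its best-scoring local
segment (Kadane over CIGAR ops under the toolkit scoring scheme), which
gives true local semantics: poorly matching query ends are clipped
rather than dragged into the alignment.

Identity is column-inclusive ("BLAST identity"): matched columns over
all alignment columns, counting inserted and deleted bases in the
denominator. Every reported hit's identity is recomputable from its
CIGAR, which is the contract the rest of the toolkit relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import edlib

from .seqio import (
    GenomicInterval,
    Sequence,
    cigar_to_string,
    parse_cigar,
    reverse_complement,
)

# Default scoring: match +1, mismatch -2, gap open -4, gap extend -1.
MATCH = 1
MISMATCH = -2
GAP_OPEN = -4
GAP_EXTEND = -1

DEFAULT_SEED_K = 15


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a query and a target sequence.

    ``query_interval`` is always on the forward strand of the query;
    ``target_interval`` on the forward strand of the target. ``strand``
    '-' means the query matches the reverse complement of the target
    span. The CIGAR is written query-against-forward-target for '+'
    hits and reverse-complemented-query-against-forward-target for '-'
    hits (ops I consume query, D consume target).
    """

    query_id: str
    target_id: str
    query_interval: GenomicInterval
    target_interval: GenomicInterval
    strand: str
    identity: float
    aligned_columns: int
    cigar: str
    score: float
    mismatches: int = 0

    @property
    def query_span(self) -> int:
        return self.query_interval.length

    @property
    def target_span(self) -> int:
        return self.target_interval.length


def identity_from_cigar(cigar: str, mismatch_count: Optional[int] = None) -> float:
    """Column-inclusive identity from a CIGAR string.

    identity = matched columns / (matches + mismatches + inserted +
    deleted bases). If the CIGAR uses ambiguous M ops, the mismatch
    count must be supplied; with =/X ops it is read off directly.
    """
    pairs = parse_cigar(cigar)
    m_cols = sum(c for op, c in pairs if op == "M")
    eq = sum(c for op, c in pairs if op == "=")
    x = sum(c for op, c in pairs if op == "X")
    indel = sum(c for op, c in pairs if op in "ID")
    if m_cols:
        if mismatch_count is None:
            raise ValueError("CIGAR contains M ops; mismatch_count required")
        matched = m_cols - mismatch_count + eq
        x += mismatch_count
    else:
        matched = eq
    columns = matched + x + indel
    if columns == 0:
        raise ValueError("CIGAR has no alignment columns")
    return matched / columns


def score_from_cigar(cigar: str) -> int:
    """Alignment score under the toolkit scheme (affine gaps)."""
    score = 0
    for op, c in parse_cigar(cigar):
        if op == "=":
            score += MATCH * c
        elif op in "XM":
            score += MISMATCH * c
        elif op in "ID":
            score += GAP_OPEN + GAP_EXTEND * (c - 1)
    return score


def _op_score(op: str, c: int) -> int:
    if op == "=":
        return MATCH * c
    if op in "XM":
        return MISMATCH * c
    return GAP_OPEN + GAP_EXTEND * (c - 1)


def _trim_to_local(pairs: list[tuple[str, int]]) -> tuple[list[tuple[str, int]], int, int, int, int]:
    """Best-scoring contiguous run of CIGAR ops (Kadane at op granularity).

    Returns (trimmed pairs, query offset, query consumed, target offset,
    target consumed) where offsets count bases clipped off the start.
    """
    best_score, best_i, best_j = 0, 0, 0
    run_score, run_start = 0, 0
    for idx, (op, c) in enumerate(pairs):
        if run_score <= 0:
            run_score, run_start = 0, idx
        run_score += _op_score(op, c)
        if run_score > best_score:
            best_score, best_i, best_j = run_score, run_start, idx + 1
    if best_j == 0:  # nothing positive; keep everything (caller filters)
        best_i, best_j = 0, len(pairs)
    q_off = sum(c for op, c in pairs[:best_i] if op in "M=XI")
    t_off = sum(c for op, c in pairs[:best_i] if op in "M=XD")
    kept = pairs[best_i:best_j]
    q_len = sum(c for op, c in kept if op in "M=XI")
    t_len = sum(c for op, c in kept if op in "M=XD")
    return kept, q_off, q_len, t_off, t_len


def _seed_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _diagonal_clusters(matches: list[tuple[int, int]], band: int, qlen: int):
    """Group (qpos, tpos) seed matches into diagonal clusters.

    Matches are grouped when their diagonals lie within ``band`` AND
    their target positions are within one query length; tandem arrays
    then yield one cluster per repeat copy offset.
    """
    if not matches:
        return []
    matches = sorted(matches, key=lambda m: (m[1] - m[0], m[1]))
    clusters = []
    current = [matches[0]]
    for m in matches[1:]:
        prev = current[-1]
        if (m[1] - m[0]) - (prev[1] - prev[0]) <= band and abs(m[1] - prev[1]) <= qlen + band:
            current.append(m)
        else:
            clusters.append(current)
            current = [m]
    clusters.append(current)
    return clusters


def _align_one_strand(
    qseq: str,
    target: Sequence,
    seed_k: int,
    band: int,
    index: dict[str, list[int]],
    max_candidates: Optional[int] = None,
) -> list[dict]:
    """Candidate raw alignments of qseq (already oriented) on forward target."""
    qlen = len(qseq)
    matches: list[tuple[int, int]] = []
    step = max(1, seed_k // 3)
    for qpos in range(0, qlen - seed_k + 1, step):
        kmer = qseq[qpos : qpos + seed_k]
        if "N" in kmer:
            continue
        for tpos in index.get(kmer, ()):
            matches.append((qpos, tpos))
    raw = []
    seen_windows = set()
    clusters = _diagonal_clusters(matches, band, qlen)
    if max_candidates is not None and len(clusters) > max_candidates:
        # keep the seed-richest clusters; tandem-repeat phase shifts
        # produce many near-duplicate weaker clusters
        clusters = sorted(clusters, key=len, reverse=True)[:max_candidates]
    for cluster in clusters:
        starts = [t - q for q, t in cluster]
        margin = band + 50 + qlen // 20
        w_start = max(0, min(starts) - margin)
        w_end = min(len(target.seq), max(starts) + qlen + margin)
        key = (w_start // 50, w_end // 50)
        if key in seen_windows:
            continue
        seen_windows.add(key)
        window = target.seq[w_start:w_end]
        res = edlib.align(qseq, window, mode="HW", task="path")
        if res["editDistance"] < 0 or not res.get("cigar"):
            continue
        t0, t1 = res["locations"][0]
        pairs = parse_cigar(res["cigar"])
        kept, q_off, q_len, t_off, t_len = _trim_to_local(pairs)
        if q_len == 0 or t_len == 0:
            continue
        raw.append(
            {
                "q_start": q_off,
                "q_end": q_off + q_len,
                "t_start": w_start + t0 + t_off,
                "t_end": w_start + t0 + t_off + t_len,
                "cigar": cigar_to_string(kept),
            }
        )
    return raw


def align_local(
    query: Sequence,
    target: Sequence,
    min_identity: float = 0.0,
    min_length: int = 0,
    seed_k: int = DEFAULT_SEED_K,
    band: int = 50,
    target_index: Optional[dict[str, list[int]]] = None,
    max_candidates: Optional[int] = None,
) -> list[AlignmentHit]:
    """Local alignments of ``query`` against both strands of ``target``.

    Hits satisfy identity >= min_identity and aligned columns >=
    min_length, and are sorted by score descending with deterministic
    tie-breaking (leftmost target start, then '+' strand first).
    Absence of hits returns an empty list, never an error.

    ``target_index`` may carry a precomputed seed index (from
    :func:`build_target_index`) to amortize repeated queries.
    """
    if not query.seq or not target.seq:
        raise ValueError("query and target must be non-empty")
    index = target_index if target_index is not None else _seed_index(target.seq, seed_k)
    qlen = len(query.seq)
    hits: list[AlignmentHit] = []
    for strand in "+-":
        qseq = query.seq if strand == "+" else reverse_complement(query.seq)
        for r in _align_one_strand(qseq, target, seed_k, band, index, max_candidates):
            ident = identity_from_cigar(r["cigar"])
            cols = sum(
                c for op, c in parse_cigar(r["cigar"]) if op in "M=XID"
            )
            if ident < min_identity or cols < min_length:
                continue
            if strand == "+":
                q_iv = GenomicInterval(query.id, r["q_start"], r["q_end"], "+")
            else:
                q_iv = GenomicInterval(
                    query.id, qlen - r["q_end"], qlen - r["q_start"], "-"
                )
            mism = sum(c for op, c in parse_cigar(r["cigar"]) if op == "X")
            hits.append(
                AlignmentHit(
                    query_id=query.id,
                    target_id=target.id,
                    query_interval=q_iv,
                    target_interval=GenomicInterval(
                        target.id, r["t_start"], r["t_end"], "+"
                    ),
                    strand=strand,
                    identity=ident,
                    aligned_columns=cols,
                    cigar=r["cigar"],
                    score=score_from_cigar(r["cigar"]),
                    mismatches=mism,
                )
            )
    hits = _dedupe(hits)
    hits.sort(
        key=lambda h: (
            -h.score,
            h.target_interval.start,
            0 if h.strand == "+" else 1,
        )
    )
    return hits


def build_target_index(target: Sequence, seed_k: int = DEFAULT_SEED_K) -> dict[str, list[int]]:
    """Precompute the exact-seed index of a target for repeated queries."""
    return _seed_index(target.seq, seed_k)


def _dedupe(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Drop hits whose target span is nearly contained in a better hit."""
    kept: list[AlignmentHit] = []
    for h in sorted(hits, key=lambda h: -h.score):
        redundant = False
        for k in kept:
            if k.strand != h.strand:
                continue
            ov = min(k.target_interval.end, h.target_interval.end) - max(
                k.target_interval.start, h.target_interval.start
            )
            if ov > 0.9 * h.target_interval.length:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def hits_to_tsv(hits: list[AlignmentHit], path) -> None:
    """PAF-like TSV dump of alignment hits."""
    with open(path, "w") as fh:
        fh.write(
            "query\tq_start\tq_end\ttarget\tt_start\tt_end\tstrand\t"
            "identity\taligned_columns\tscore\tcigar\n"
        )
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.query_interval.start}\t{h.query_interval.end}\t"
                f"{h.target_id}\t{h.target_interval.start}\t{h.target_interval.end}\t"
                f"{h.strand}\t{h.identity:.6f}\t{h.aligned_columns}\t{h.score}\t{h.cigar}\n"
            )
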