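"""Satellite monomer decomposition, clustering, and identity heatmaps.

Monomers are delimited by aligning a satellite consensus (the 178-bp
centromeric CEN180 unit or the ~0.5-kb 5S rDNA unit) against both
strands of a genome, keeping hits that cover >= 90% of the consensus
and fall in the preset length window (165-185 bp for CEN180, 490-510
bp for 5S). Retained monomers are projected onto consensus columns to
form a gapped alignment matrix, which is clustered with a per-column
multinomial mixture fitted by EM; the cluster count K* is selected by
the BIC inflection (the K maximizing the discrete second difference
of the BIC curve). Windowed pairwise-identity heatmaps expose
higher-order array structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import edlib
import numpy as np

from .align import (
    AlignmentHit,
    align_local,
    build_target_index,
    identity_from_cigar,
)
from .seqio import (
    GenomicInterval,
    Sequence,
    parse_cigar,
    reverse_complement,
)

# The 178-bp A. thaliana centromeric satellite consensus.
CEN180_CONSENSUS = (
    "AAAAGCCTAAGTATTGTTTCCTTGTTAGAAGATACAAAGACAAAGACTCATATGGACTTCGGCTACACC"
    "ATCAAAGCTTTGAGAAGCAAGAAGAAGCTTGGTTAGTGTTTTGGAGTCAAATATGACTTGATGTCATGT"
    "GTATGATTGAGTATAACAACTTAAACCGCAACCGGATCTT"
)

SYMBOLS = "ACGT-"
_SYM_INDEX = {c: i for i, c in enumerate(SYMBOLS)}


@dataclass(frozen=True)
class SatelliteConsensus:
    """A satellite unit with its retention policy."""

    name: str
    seq: str
    length_range: tuple[int, int]
    min_query_coverage: float = 0.90

    @classmethod
    def cen180(cls) -> "SatelliteConsensus":
        return cls("CEN180", CEN180_CONSENSUS, (165, 185), 0.90)

    @classmethod
    def rdna_5s(cls, seq: str) -> "SatelliteConsensus":
        return cls("5S", seq, (490, 510), 0.90)


@dataclass(frozen=True)
class SatelliteMonomer:
    """One unit copy of a tandem satellite, consensus-oriented."""

    locus: GenomicInterval
    strand: str
    identity_to_consensus: float
    sequence: str  # reverse-complemented to consensus orientation when '-'

    @property
    def length(self) -> int:
        return self.locus.length


@dataclass
class MonomerAlignmentMatrix:
    """Monomers x consensus-column symbol matrix over {A,C,G,T,-}."""

    rows: list[str]
    monomers: list[SatelliteMonomer]
    n_columns: int

    def to_codes(self) -> np.ndarray:
        arr = np.empty((len(self.rows), self.n_columns), dtype=np.int8)
        for i, row in enumerate(self.rows):
            arr[i] = [_SYM_INDEX.get(c, _SYM_INDEX["-"]) for c in row]
        return arr


@dataclass
class ClusterResult:
    k_range: list[int]
    bic: dict[int, float]
    log_likelihood: dict[int, float]
    k_star: int
    labels: np.ndarray
    cluster_consensus: dict[int, str]
    degenerate: bool = False


def find_monomers(
    genome: Iterable[Sequence],
    consensus: SatelliteConsensus,
    max_overlap_fraction: float = 0.10,
) -> list[SatelliteMonomer]:
    """Consensus occurrences resolved to non-overlapping monomers.

    Hits on both strands with query coverage >= the preset minimum are
    resolved greedily by score (hits overlapping a retained hit by
    more than ``max_overlap_fraction`` of their own length are
    dropped) and retained iff their genomic length falls inside the
    preset window. Sorted by coordinate.
    """
    query = Sequence(consensus.name, consensus.seq)
    out: list[SatelliteMonomer] = []
    for target in genome:
        hits = align_local(query, target, min_identity=0.5)
        qlen = len(consensus.seq)
        hits = [
            h for h in hits if h.query_interval.length / qlen >= consensus.min_query_coverage
        ]
        kept: list[AlignmentHit] = []
        for h in sorted(hits, key=lambda h: (-h.score, h.target_interval.start)):
            ok = True
            for k in kept:
                ov = min(k.target_interval.end, h.target_interval.end) - max(
                    k.target_interval.start, h.target_interval.start
                )
                if ov > max_overlap_fraction * h.target_interval.length:
                    ok = False
                    break
            if ok:
                kept.append(h)
        lo, hi = consensus.length_range
        for h in kept:
            span = h.target_interval
            if not lo <= span.length <= hi:
                continue
            seq = target.seq[span.start : span.end]
            if h.strand == "-":
                seq = reverse_complement(seq)
            out.append(
                SatelliteMonomer(
                    locus=GenomicInterval(target.id, span.start, span.end, h.strand),
                    strand=h.strand,
                    identity_to_consensus=h.identity,
                    sequence=seq,
                )
            )
    out.sort(key=lambda m: (m.locus.seq_id, m.locus.start))
    return out


def _project_onto_consensus(monomer_seq: str, consensus_seq: str) -> Optional[str]:
    """Row of consensus-column symbols for one monomer.

    The monomer is globally aligned to the consensus; deletions
    relative to the consensus become '-' columns, insertions are
    collapsed (they have no consensus column). Returns None when
    identity < 0.5.
    """
    res = edlib.align(monomer_seq, consensus_seq, mode="NW", task="path")
    cigar = res["cigar"]
    if identity_from_cigar(cigar) < 0.5:
        return None
    row: list[str] = []
    qi = 0
    for op, c in parse_cigar(cigar):
        if op in "=XM":
            row.extend(monomer_seq[qi : qi + c])
            qi += c
        elif op == "I":  # monomer insertion: no consensus column
            qi += c
        elif op == "D":  # consensus base missing in monomer
            row.extend("-" * c)
    return "".join(row)


def build_monomer_alignment(
    monomers: list[SatelliteMonomer], consensus: SatelliteConsensus
) -> MonomerAlignmentMatrix:
    """Consensus-anchored alignment matrix of the monomer set.

    Each monomer is aligned pairwise to the consensus and projected
    onto the consensus columns, so all rows share one coordinate
    system without a progressive MSA. Monomers aligning at < 0.5
    identity are excluded with a warning.
    """
    if len(monomers) < 2:
        raise ValueError("need at least 2 monomers")
    rows: list[str] = []
    kept: list[SatelliteMonomer] = []
    for m in monomers:
        row = _project_onto_consensus(m.sequence, consensus.seq)
        if row is None:
            import logging

            logging.getLogger("anchorfill").warning(
                "monomer %s:%d-%d below 0.5 identity; excluded",
                m.locus.seq_id,
                m.locus.start,
                m.locus.end,
            )
            continue
        rows.append(row)
        kept.append(m)
    return MonomerAlignmentMatrix(rows, kept, len(consensus.seq))


def _flat_onehot(codes: np.ndarray) -> np.ndarray:
    n, n_cols = codes.shape
    S = len(SYMBOLS)
    onehot = np.zeros((n, n_cols, S))
    onehot[np.arange(n)[:, None], np.arange(n_cols)[None, :], codes] = 1.0
    return onehot.reshape(n, n_cols * S)


class MultinomialMixture:
    """Per-column independent multinomial mixture over {A,C,G,T,-}.

    A small fit/predict estimator: ``fit`` runs EM with restarts on an
    integer-coded matrix (n_rows x n_columns, codes 0..4), keeping the
    best log-likelihood; ``predict`` returns hard labels. BIC uses
    p = (K-1) + K * n_columns * (S-1) free parameters.
    """

    def __init__(
        self,
        n_components: int,
        n_init: int = 10,
        max_iter: int = 200,
        tol: float = 1e-6,
        alpha: float = 0.1,
        random_state: Optional[np.random.Generator] = None,
    ):
        self.n_components = n_components
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.alpha = alpha  # Laplace smoothing of the column multinomials
        self.random_state = random_state

    def _e_step(self, onehot: np.ndarray, log_theta: np.ndarray, log_pi: np.ndarray):
        # onehot: n x (C*S) flat; log_theta: K x C x S
        n = onehot.shape[0]
        logp = onehot @ log_theta.reshape(self.n_components, -1).T + log_pi
        mx = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - mx)
        tot = p.sum(axis=1, keepdims=True)
        resp = p / tot
        ll = float((np.log(tot).squeeze(1) + mx.squeeze(1)).sum())
        return resp, ll

    def _m_step(self, onehot: np.ndarray, resp: np.ndarray, n_cols: int):
        n = onehot.shape[0]
        pi = resp.sum(axis=0) / n
        S = len(SYMBOLS)
        counts = (resp.T @ onehot).reshape(self.n_components, n_cols, S) + self.alpha
        theta = counts / counts.sum(axis=2, keepdims=True)
        return np.log(np.maximum(pi, 1e-300)), np.log(theta)

    def fit(self, codes: np.ndarray) -> "MultinomialMixture":
        rng = self.random_state or np.random.default_rng()
        n, n_cols = codes.shape
        onehot = _flat_onehot(codes)
        best_ll = -np.inf
        best = None
        for _ in range(self.n_init):
            # init: responsibilities from a random hard assignment
            assign = rng.integers(0, self.n_components, size=n)
            resp = np.zeros((n, self.n_components))
            resp[np.arange(n), assign] = 1.0
            resp += 0.05 * rng.random((n, self.n_components))
            resp /= resp.sum(axis=1, keepdims=True)
            ll_prev = -np.inf
            for _it in range(self.max_iter):
                log_pi, log_theta = self._m_step(onehot, resp, n_cols)
                resp, ll = self._e_step(onehot, log_theta, log_pi)
                if abs(ll - ll_prev) < self.tol * max(1.0, abs(ll)):
                    break
                ll_prev = ll
            if ll > best_ll:
                best_ll = ll
                best = (log_pi, log_theta)
        self.log_pi_, self.log_theta_ = best
        self.log_likelihood_ = best_ll
        resp, _ = self._e_step(onehot, self.log_theta_, self.log_pi_)
        self.labels_ = resp.argmax(axis=1)
        return self

    def predict(self, codes: np.ndarray) -> np.ndarray:
        resp, _ = self._e_step(_flat_onehot(codes), self.log_theta_, self.log_pi_)
        return resp.argmax(axis=1)

    def n_parameters(self, n_columns: int) -> int:
        return (self.n_components - 1) + self.n_components * n_columns * (len(SYMBOLS) - 1)

    def bic(self, n_rows: int, n_columns: int) -> float:
        return -2.0 * self.log_likelihood_ + self.n_parameters(n_columns) * np.log(n_rows)


def _single_component_fit(codes: np.ndarray, alpha: float = 0.1):
    """Closed-form K=1 fit (no EM): per-column multinomial MLE."""
    n, n_cols = codes.shape
    S = len(SYMBOLS)
    ll = 0.0
    for c in range(n_cols):
        counts = np.bincount(codes[:, c], minlength=S).astype(float) + alpha
        p = counts / counts.sum()
        obs = np.bincount(codes[:, c], minlength=S)
        ll += float((obs * np.log(p)).sum())
    p_params = n_cols * (S - 1)
    bic = -2.0 * ll + p_params * np.log(n)
    return ll, bic


def cluster_monomers(
    matrix: MonomerAlignmentMatrix,
    k_range: range = range(2, 11),
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> ClusterResult:
    """Cluster monomers and select K by the BIC inflection.

    For each K in ``k_range`` a multinomial mixture is fitted by EM
    (``n_init`` restarts, best log-likelihood kept). A single-component
    fit (closed form) extends the curve below min(k_range) so the
    smallest candidate K is interior to it. K* maximizes the discrete
    second difference BIC(K-1) - 2*BIC(K) + BIC(K+1) over candidate K;
    ties break toward smaller K. Identical rows short-circuit to
    K* = min(k_range) with the degenerate flag set.
    """
    codes = matrix.to_codes()
    n = codes.shape[0]
    ks = sorted(k_range)
    if n < max(ks):
        raise ValueError(f"need at least {max(ks)} monomers, got {n}")
    if all(r == matrix.rows[0] for r in matrix.rows):
        return ClusterResult(
            k_range=ks,
            bic={},
            log_likelihood={},
            k_star=min(ks),
            labels=np.zeros(n, dtype=int),
            cluster_consensus={0: matrix.rows[0].replace("-", "")},
            degenerate=True,
        )
    rng = np.random.default_rng(seed)
    bic: dict[int, float] = {}
    ll: dict[int, float] = {}
    models: dict[int, MultinomialMixture] = {}
    ll1, bic1 = _single_component_fit(codes)
    bic[1], ll[1] = bic1, ll1
    for k in ks:
        model = MultinomialMixture(
            k, n_init=n_init, max_iter=max_iter, tol=tol, random_state=rng
        ).fit(codes)
        models[k] = model
        bic[k] = model.bic(n, codes.shape[1])
        ll[k] = model.log_likelihood_
    candidates = [k for k in ks if (k - 1) in bic and (k + 1) in bic]
    if not candidates:
        k_star = ks[0]
    else:
        second_diff = {k: bic[k - 1] - 2 * bic[k] + bic[k + 1] for k in candidates}
        k_star = max(candidates, key=lambda k: (second_diff[k], -k))
    labels = models[k_star].labels_
    consensus: dict[int, str] = {}
    for cid in range(k_star):
        members = codes[labels == cid]
        if members.size == 0:
            continue
        cols = []
        for c in range(codes.shape[1]):
            counts = np.bincount(members[:, c], minlength=len(SYMBOLS))
            cols.append(SYMBOLS[int(counts.argmax())])
        consensus[cid] = "".join(cols).replace("-", "")
    return ClusterResult(
        k_range=ks,
        bic={k: float(v) for k, v in bic.items()},
        log_likelihood={k: float(v) for k, v in ll.items()},
        k_star=k_star,
        labels=labels,
        cluster_consensus=consensus,
    )


def identity_heatmap(
    region: Sequence,
    window: int = 5000,
    min_identity: float = 0.5,
    min_length_fraction: float = 0.5,
) -> np.ndarray:
    """Pairwise best local-alignment identity between fixed windows.

    The region is tiled into non-overlapping windows; entry (i, j) is
    the best local-alignment identity between windows i and j, or 0
    when no alignment of at least ``min_length_fraction`` of a window
    at ``min_identity`` exists. Symmetric with unit diagonal.
    """
    if len(region.seq) < 2 * window:
        raise ValueError("region shorter than two windows")
    n = len(region.seq) // window
    wins = [
        Sequence(f"w{i}", region.seq[i * window : (i + 1) * window]) for i in range(n)
    ]
    mat = np.zeros((n, n))
    np.fill_diagonal(mat, 1.0)
    min_len = int(min_length_fraction * window)
    for i in range(n):
        for j in range(i + 1, n):
            hits = align_local(
                wins[i], wins[j], min_identity=min_identity, min_length=min_len,
                max_candidates=5,
            )
            val = hits[0].identity if hits else 0.0
            mat[i, j] = mat[j, i] = val
    return mat


def monomers_bed(monomers: list[SatelliteMonomer], path, labels=None) -> None:
    from .seqio import write_bed

    ivs = []
    for i, m in enumerate(monomers):
        name = str(labels[i]) if labels is not None else "."
        ivs.append(
            GenomicInterval(
                m.locus.seq_id,
                m.locus.start,
                m.locus.end,
                m.strand,
                name,
                f"{m.identity_to_consensus:.4f}",
            )
        )
    write_bed(ivs, path)
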