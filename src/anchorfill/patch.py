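"""Anchor-guided gap filling and region replacement.

The strategy mirrors how finished assemblies are patched from an
orthogonal contig set: for each N-gap in the draft, find two uniquely
placed anchor sequences (BAC-like clones) that align at very high
identity (default > 99.9%) both to the draft, flanking the gap, and to
a single donor contig, in the same relative order and orientation
("concordantly"). The donor sequence between the anchors then replaces
the corresponding draft span; alternatively the whole donor contig
replaces the region (whole-contig mode). Every edit is recorded as an
auditable PatchPlan plus a liftover table mapping old draft
coordinates to the patched assembly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .align import AlignmentHit, align_local, build_target_index
from .seqio import GenomicInterval, Sequence, reverse_complement

logger = logging.getLogger("anchorfill")

_N_RUN = re.compile(r"N+")

DEFAULT_MIN_IDENTITY = 0.999
# An anchor is "unique" when any second-best placement is clearly worse.
SECOND_BEST_IDENTITY = 0.98
SECOND_BEST_COVERAGE = 0.5


@dataclass(frozen=True)
class GapRecord:
    """A maximal N-run in a scaffold."""

    scaffold_id: str
    interval: GenomicInterval

    @property
    def n_run_length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class AnchorPair:
    """Two anchors flanking a gap, concordant between draft and donor."""

    left_anchor_id: str
    right_anchor_id: str
    draft_left: AlignmentHit
    draft_right: AlignmentHit
    donor_left: AlignmentHit
    donor_right: AlignmentHit
    donor_id: str
    orientation: str  # "same" | "inverted"


@dataclass(frozen=True)
class PatchPlan:
    """One auditable replacement instruction."""

    scaffold_id: str
    replaced_span: GenomicInterval
    donor_id: str
    donor_span: GenomicInterval
    donor_orientation: str  # "same" | "inverted"
    mode: str  # "span" | "whole_contig"
    provenance: dict


@dataclass
class LiftoverSegment:
    old_start: int
    old_end: int
    new_start: int  # -1 when the segment was replaced (maps to nothing)

    @property
    def offset(self) -> Optional[int]:
        return None if self.new_start < 0 else self.new_start - self.old_start


@dataclass
class LiftoverTable:
    """Old-draft -> patched-assembly coordinate map for one scaffold."""

    scaffold_id: str
    segments: list[LiftoverSegment] = field(default_factory=list)

    def lift(self, pos: int) -> Optional[int]:
        for seg in self.segments:
            if seg.old_start <= pos < seg.old_end:
                return None if seg.new_start < 0 else seg.new_start + (pos - seg.old_start)
        raise ValueError(f"position {pos} outside the old sequence")

    def inverse_lift(self, new_pos: int) -> Optional[int]:
        for seg in self.segments:
            if seg.new_start < 0:
                continue
            new_end = seg.new_start + (seg.old_end - seg.old_start)
            if seg.new_start <= new_pos < new_end:
                return seg.old_start + (new_pos - seg.new_start)
        return None


def find_gaps(assembly: Iterable[Sequence], min_n_run: int = 10) -> list[GapRecord]:
    """Maximal N-runs of at least ``min_n_run`` bp, in coordinate order."""
    gaps: list[GapRecord] = []
    for seq in assembly:
        for m in _N_RUN.finditer(seq.seq):
            if m.end() - m.start() >= min_n_run:
                gaps.append(
                    GapRecord(seq.id, GenomicInterval(seq.id, m.start(), m.end()))
                )
    return gaps


MIN_ANCHOR_COVERAGE = 0.9


def _unique_best_hit(hits: list[AlignmentHit], min_identity: float, anchor_len: int):
    """Best hit if it passes the identity gate, covers (nearly) the whole
    anchor, and is uniquely placed."""
    qualifying = [
        h
        for h in hits
        if h.identity > min_identity
        and h.query_interval.length >= MIN_ANCHOR_COVERAGE * anchor_len
    ]
    if not qualifying:
        return None
    best = qualifying[0]
    for other in hits[1:]:
        if other is best:
            continue
        same_locus = (
            other.target_id == best.target_id
            and min(other.target_interval.end, best.target_interval.end)
            - max(other.target_interval.start, best.target_interval.start)
            > 0
        )
        if same_locus:
            continue
        if (
            other.identity >= SECOND_BEST_IDENTITY
            and other.query_interval.length >= SECOND_BEST_COVERAGE * anchor_len
        ):
            return None  # ambiguous placement
    return best


def select_anchor_pair(
    gap: GapRecord,
    anchors: list[Sequence],
    draft: Sequence,
    donors: list[Sequence],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    draft_index=None,
    donor_indexes: Optional[dict] = None,
) -> Optional[AnchorPair]:
    """Concordant anchor pair flanking ``gap``, or None.

    Among all qualifying pairs the one with the smallest combined
    gap-to-anchor distance is returned. Anchors with ambiguous
    (repeat-like) placements are excluded.
    """
    if draft_index is None:
        draft_index = build_target_index(draft)
    lefts: list[tuple[int, Sequence, AlignmentHit]] = []
    rights: list[tuple[int, Sequence, AlignmentHit]] = []
    for anchor in anchors:
        hits = align_local(
            anchor, draft, min_identity=0.9, target_index=draft_index
        )
        best = _unique_best_hit(hits, min_identity, len(anchor))
        if best is None:
            continue
        iv = best.target_interval
        if iv.end <= gap.interval.start:
            lefts.append((gap.interval.start - iv.end, anchor, best))
        elif iv.start >= gap.interval.end:
            rights.append((iv.start - gap.interval.end, anchor, best))
    lefts.sort(key=lambda t: t[0])
    rights.sort(key=lambda t: t[0])

    donor_indexes = donor_indexes if donor_indexes is not None else {}
    best_pair: Optional[AnchorPair] = None
    best_dist = None
    for dist_l, anc_l, hit_l in lefts:
        for dist_r, anc_r, hit_r in rights:
            if best_dist is not None and dist_l + dist_r >= best_dist:
                continue
            pair = _pair_on_donor(
                anc_l, hit_l, anc_r, hit_r, donors, min_identity, donor_indexes
            )
            if pair is not None:
                best_pair, best_dist = pair, dist_l + dist_r
    if best_pair is None:
        logger.info(
            "no concordant anchor pair for gap %s:%d-%d",
            gap.scaffold_id,
            gap.interval.start,
            gap.interval.end,
        )
    return best_pair


def _pair_on_donor(anc_l, hit_l, anc_r, hit_r, donors, min_identity, donor_indexes):
    for donor in donors:
        if donor.id not in donor_indexes:
            donor_indexes[donor.id] = build_target_index(donor)
        idx = donor_indexes[donor.id]
        dl = _unique_best_hit(
            align_local(anc_l, donor, min_identity=0.9, target_index=idx),
            min_identity,
            len(anc_l),
        )
        dr = _unique_best_hit(
            align_local(anc_r, donor, min_identity=0.9, target_index=idx),
            min_identity,
            len(anc_r),
        )
        if dl is None or dr is None:
            continue
        # Concordance: same relative orientation and same relative order
        # of the two anchors on draft and donor.
        rel_draft = (hit_l.strand, hit_r.strand)
        if dl.strand == rel_draft[0] and dr.strand == rel_draft[1]:
            orientation = "same"
            ordered = dl.target_interval.end <= dr.target_interval.start
        elif dl.strand != rel_draft[0] and dr.strand != rel_draft[1]:
            orientation = "inverted"
            ordered = dr.target_interval.end <= dl.target_interval.start
        else:
            continue
        if not ordered:
            continue
        return AnchorPair(
            left_anchor_id=anc_l.id,
            right_anchor_id=anc_r.id,
            draft_left=hit_l,
            draft_right=hit_r,
            donor_left=dl,
            donor_right=dr,
            donor_id=donor.id,
            orientation=orientation,
        )
    return None


def plan_from_pair(pair: AnchorPair, mode: str = "span", donor_length: int = 0) -> PatchPlan:
    """Turn a concordant anchor pair into a replacement instruction.

    In span mode the replaced draft span and the donor span both run
    between the inner anchor boundaries; in whole_contig mode the donor
    span is the full contig and the draft span runs from the left
    anchor's start to the right anchor's end.
    """
    if mode not in {"span", "whole_contig"}:
        raise ValueError(f"unknown mode {mode!r}")
    draft_iv = GenomicInterval(
        pair.draft_left.target_id,
        pair.draft_left.target_interval.end if mode == "span" else pair.draft_left.target_interval.start,
        pair.draft_right.target_interval.start if mode == "span" else pair.draft_right.target_interval.end,
    )
    if mode == "span":
        if pair.orientation == "same":
            d_start = pair.donor_left.target_interval.end
            d_end = pair.donor_right.target_interval.start
        else:
            d_start = pair.donor_right.target_interval.end
            d_end = pair.donor_left.target_interval.start
    else:
        d_start, d_end = 0, donor_length
    donor_iv = GenomicInterval(pair.donor_id, d_start, d_end)
    return PatchPlan(
        scaffold_id=pair.draft_left.target_id,
        replaced_span=draft_iv,
        donor_id=pair.donor_id,
        donor_span=donor_iv,
        donor_orientation=pair.orientation,
        mode=mode,
        provenance={
            "left_anchor": pair.left_anchor_id,
            "right_anchor": pair.right_anchor_id,
            "draft_identities": (pair.draft_left.identity, pair.draft_right.identity),
            "donor_identities": (pair.donor_left.identity, pair.donor_right.identity),
        },
    )


def apply_patch(
    draft: Sequence, donor: Sequence, plan: PatchPlan
) -> tuple[Sequence, LiftoverTable]:
    """Splice the donor span into the draft according to ``plan``."""
    if plan.scaffold_id != draft.id or plan.donor_id != donor.id:
        raise ValueError("plan does not match the provided sequences")
    rs = plan.replaced_span
    ds = plan.donor_span
    if rs.end > len(draft.seq) or ds.end > len(donor.seq):
        raise ValueError("plan coordinates stale: spans exceed sequence lengths")
    insert = donor.seq[ds.start : ds.end]
    if plan.donor_orientation == "inverted":
        insert = reverse_complement(insert)
    patched = draft.seq[: rs.start] + insert + draft.seq[rs.end :]
    shift = len(insert) - rs.length
    table = LiftoverTable(
        draft.id,
        [
            LiftoverSegment(0, rs.start, 0),
            LiftoverSegment(rs.start, rs.end, -1),
            LiftoverSegment(rs.end, len(draft.seq), rs.end + shift),
        ],
    )
    return Sequence(draft.id, patched), table


@dataclass
class PatchReport:
    filled: list[dict] = field(default_factory=list)
    unfilled: list[GapRecord] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)
    liftover: dict[str, LiftoverTable] = field(default_factory=dict)

    @property
    def remaining_gap_count(self) -> int:
        return len(self.unfilled)


def _compose_liftover(
    scaffold_id: str, old_length: int, plans: list[PatchPlan]
) -> LiftoverTable:
    """Old-draft -> patched mapping across all applied plans.

    Plans carry original draft coordinates; the new coordinate of a
    conserved segment shifts by the cumulative length change of the
    replacements upstream of it.
    """
    segments: list[LiftoverSegment] = []
    pos = 0
    shift = 0
    for plan in sorted(plans, key=lambda p: p.replaced_span.start):
        rs = plan.replaced_span
        if rs.start > pos:
            segments.append(LiftoverSegment(pos, rs.start, pos + shift))
        segments.append(LiftoverSegment(rs.start, rs.end, -1))
        shift += plan.donor_span.length - rs.length
        pos = rs.end
    if pos < old_length:
        segments.append(LiftoverSegment(pos, old_length, pos + shift))
    return LiftoverTable(scaffold_id, segments)


def patch_all(
    draft_assembly: list[Sequence],
    donors: list[Sequence],
    anchors: list[Sequence],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    mode: str = "span",
    min_n_run: int = 10,
) -> tuple[list[Sequence], PatchReport]:
    """Fill every gap with a qualifying anchor pair; report the rest.

    Gaps are processed per scaffold in coordinate order. Candidate
    plans overlapping an already applied plan are resolved in favour of
    the higher combined anchor identity; the loser is logged.
    """
    report = PatchReport()
    out: list[Sequence] = []
    for scaffold in draft_assembly:
        gaps = find_gaps([scaffold], min_n_run=min_n_run)
        plans: list[tuple[GapRecord, PatchPlan]] = []
        draft_index = build_target_index(scaffold)
        donor_indexes: dict = {}
        for gap in gaps:
            pair = select_anchor_pair(
                gap,
                anchors,
                scaffold,
                donors,
                min_identity=min_identity,
                draft_index=draft_index,
                donor_indexes=donor_indexes,
            )
            if pair is None:
                report.unfilled.append(gap)
                continue
            donor_len = next(len(d.seq) for d in donors if d.id == pair.donor_id)
            plan = plan_from_pair(pair, mode=mode, donor_length=donor_len)
            if not (
                plan.replaced_span.start <= gap.interval.start
                and gap.interval.end <= plan.replaced_span.end
            ):
                report.unfilled.append(gap)
                continue
            plans.append((gap, plan))
        # resolve overlaps, keep higher combined anchor identity
        def _combined_identity(plan: PatchPlan) -> float:
            prov = plan.provenance
            return sum(prov["draft_identities"]) + sum(prov["donor_identities"])

        accepted: list[tuple[GapRecord, PatchPlan]] = []
        for gap, plan in plans:
            clash = next(
                (
                    (g2, p2)
                    for g2, p2 in accepted
                    if min(p2.replaced_span.end, plan.replaced_span.end)
                    > max(p2.replaced_span.start, plan.replaced_span.start)
                ),
                None,
            )
            if clash is None:
                accepted.append((gap, plan))
            elif _combined_identity(plan) > _combined_identity(clash[1]):
                accepted.remove(clash)
                report.unfilled.append(clash[0])
                report.conflicts.append(
                    f"overlapping plans at {plan.scaffold_id}: kept gap "
                    f"{gap.interval.start}-{gap.interval.end}"
                )
                accepted.append((gap, plan))
            else:
                report.unfilled.append(gap)
                report.conflicts.append(
                    f"overlapping plans at {plan.scaffold_id}: dropped gap "
                    f"{gap.interval.start}-{gap.interval.end}"
                )
        # apply right-to-left so earlier coordinates stay valid
        current = scaffold
        for gap, plan in sorted(
            accepted, key=lambda t: -t[1].replaced_span.start
        ):
            donor = next(d for d in donors if d.id == plan.donor_id)
            current, _ = apply_patch(current, donor, plan)
            report.filled.append(
                {
                    "scaffold": scaffold.id,
                    "gap": (gap.interval.start, gap.interval.end),
                    "replaced_span": (plan.replaced_span.start, plan.replaced_span.end),
                    "donor": plan.donor_id,
                    "donor_span": (plan.donor_span.start, plan.donor_span.end),
                    "orientation": plan.donor_orientation,
                    "mode": plan.mode,
                    "provenance": plan.provenance,
                }
            )
        report.liftover[scaffold.id] = _compose_liftover(
            scaffold.id, len(scaffold.seq), [p for _, p in accepted]
        )
        out.append(current)
    return out, report


def liftover_tsv(tables: dict[str, LiftoverTable], path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\told_start\told_end\tnew_start\tnew_end\n")
        for table in tables.values():
            for seg in table.segments:
                if seg.new_start < 0:
                    fh.write(f"{table.scaffold_id}\t{seg.old_start}\t{seg.old_end}\t.\t.\n")
                else:
                    new_end = seg.new_start + (seg.old_end - seg.old_start)
                    fh.write(
                        f"{table.scaffold_id}\t{seg.old_start}\t{seg.old_end}\t"
                        f"{seg.new_start}\t{new_end}\n"
                    )
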