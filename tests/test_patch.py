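import numpy as np
import pytest

from anchorfill.patch import (
    GapRecord,
    LiftoverSegment,
    LiftoverTable,
    PatchPlan,
    apply_patch,
    find_gaps,
    patch_all,
    select_anchor_pair,
)
from anchorfill.seqio import GenomicInterval, Sequence, reverse_complement
from anchorfill.simulate import SimulationConfig, simulate


class TestFindGaps:
    def test_no_gap(self):
        assert find_gaps([Sequence("s", "ACGT")]) == []

    def test_single_gap_coordinates(self):
        gaps = find_gaps([Sequence("s", "AC" + "N" * 50 + "GT")])
        assert len(gaps) == 1
        assert (gaps[0].interval.start, gaps[0].interval.end) == (2, 52)
        assert gaps[0].n_run_length == 50

    def test_maximality_two_runs(self):
        gaps = find_gaps([Sequence("s", "A" + "N" * 10 + "C" + "N" * 10 + "G")])
        assert [(g.interval.start, g.interval.end) for g in gaps] == [(1, 11), (12, 22)]

    def test_min_run_filter(self):
        assert find_gaps([Sequence("s", "AC" + "N" * 9 + "GT")]) == []


class TestSelectAnchorPair:
    def test_planted_truth_pair_found_same_orientation(self, default_bundle):
        b = default_bundle
        gap = find_gaps([b.draft])[0]
        pair = select_anchor_pair(gap, b.anchors, b.draft, b.donors)
        assert pair is not None
        assert pair.orientation == "same"
        assert {pair.left_anchor_id, pair.right_anchor_id} == {"anchorL1", "anchorR1"}

    def test_anchor_below_identity_gate_rejected(self, default_bundle):
        b = default_bundle
        gap = find_gaps([b.draft])[0]
        # corrupt the flanking left anchor to ~99.8% identity (3 subs / 1500 bp)
        bad_anchors = []
        for a in b.anchors:
            if a.id == "anchorL1":
                chars = list(a.seq)
                for p in (100, 700, 1300):
                    chars[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[p]]
                bad_anchors.append(Sequence(a.id, "".join(chars)))
            elif a.id.endswith("1"):
                bad_anchors.append(a)
        assert select_anchor_pair(gap, bad_anchors, b.draft, b.donors) is None

    def test_inverted_donor_detected(self):
        b = simulate(SimulationConfig(seed=21, donor_inverted=(False, True, False)))
        gaps = find_gaps([b.draft])
        pair = select_anchor_pair(gaps[1], b.anchors, b.draft, b.donors)
        assert pair is not None
        assert pair.orientation == "inverted"

    def test_non_unique_anchor_rejected(self, make_dna):
        repeat = make_dna(1500, seed=9)
        u1, u2 = make_dna(3000, seed=10), make_dna(3000, seed=12)
        # repeat occurs on both sides of the gap: placement is ambiguous
        draft = Sequence("d", repeat + u1 + "N" * 500 + u2 + repeat)
        donor = Sequence("don", repeat + u1 + "X".replace("X", "") + u2 + repeat)
        gap = find_gaps([draft])[0]
        assert select_anchor_pair(gap, [Sequence("a", repeat)], draft, [donor]) is None


class TestApplyPatch:
    def test_identity_patch_is_noop(self, make_dna):
        seq = make_dna(2000)
        draft = Sequence("d", seq)
        donor = Sequence("don", seq[400:1600])
        plan = PatchPlan(
            "d",
            GenomicInterval("d", 500, 1500),
            "don",
            GenomicInterval("don", 100, 1100),
            "same",
            "span",
            {},
        )
        patched, table = apply_patch(draft, donor, plan)
        assert patched.seq == draft.seq
        assert all(s.offset in (0, None) for s in table.segments)

    def test_length_change_shifts_downstream(self, make_dna):
        draft = Sequence("d", make_dna(1000))
        donor = Sequence("don", make_dna(150, seed=3))
        plan = PatchPlan(
            "d",
            GenomicInterval("d", 200, 300),
            "don",
            GenomicInterval("don", 0, 150),
            "same",
            "span",
            {},
        )
        patched, table = apply_patch(draft, donor, plan)
        assert len(patched.seq) == 1050
        assert table.lift(300) == 350
        assert table.lift(999) == 1049
        assert table.lift(250) is None  # replaced bases map to nothing
        assert table.lift(100) == 100

    def test_stale_plan_refused(self, make_dna):
        draft = Sequence("d", make_dna(100))
        donor = Sequence("don", make_dna(50, seed=4))
        plan = PatchPlan(
            "d",
            GenomicInterval("d", 50, 200),
            "don",
            GenomicInterval("don", 0, 50),
            "same",
            "span",
            {},
        )
        with pytest.raises(ValueError, match="stale"):
            apply_patch(draft, donor, plan)

    def test_liftover_bijective_outside_replacement(self, make_dna):
        table = LiftoverTable(
            "d",
            [
                LiftoverSegment(0, 100, 0),
                LiftoverSegment(100, 200, -1),
                LiftoverSegment(200, 500, 250),
            ],
        )
        for pos in (0, 50, 99, 200, 350, 499):
            lifted = table.lift(pos)
            if lifted is not None:
                assert table.inverse_lift(lifted) == pos


class TestPatchAll:
    def test_round_trip_reconstructs_truth(self, default_bundle):
        b = default_bundle
        patched, report = patch_all([b.draft], b.donors, b.anchors)
        assert report.remaining_gap_count == 0
        assert patched[0].seq == b.truth_genome.seq

    def test_round_trip_with_inverted_donors(self):
        b = simulate(SimulationConfig(seed=31, donor_inverted=(True, False, True)))
        patched, report = patch_all([b.draft], b.donors, b.anchors)
        assert report.remaining_gap_count == 0
        assert patched[0].seq == b.truth_genome.seq

    def test_gaps_without_donor_coverage_remain(self, default_bundle):
        b = default_bundle
        patched, report = patch_all([b.draft], b.donors[:1], b.anchors)
        assert len(report.filled) == 1
        assert report.remaining_gap_count == 2
        remaining = find_gaps(patched)
        truth_gaps = {(g.start, g.end) for g in b.gap_truth[1:]}
        assert {(g.interval.start, g.interval.end) for g in remaining} == truth_gaps

    def test_empty_anchor_set_is_noop(self, default_bundle):
        b = default_bundle
        patched, report = patch_all([b.draft], b.donors, [])
        assert patched[0].seq == b.draft.seq
        assert report.remaining_gap_count == len(b.gap_truth)

    def test_idempotent_on_gap_free_assembly(self, default_bundle):
        b = default_bundle
        patched, _ = patch_all([b.draft], b.donors, b.anchors)
        again, report = patch_all(patched, b.donors, b.anchors)
        assert again[0].seq == patched[0].seq
        assert report.filled == [] and report.remaining_gap_count == 0

    def test_composed_liftover_maps_conserved_bases(self, default_bundle):
        b = default_bundle
        patched, report = patch_all([b.draft], b.donors, b.anchors)
        table = report.liftover[b.draft.id]
        rng = np.random.default_rng(0)
        for pos in rng.integers(0, len(b.draft.seq), size=200).tolist():
            new = table.lift(pos)
            if new is None:
                continue  # inside a replaced span
            assert patched[0].seq[new] == b.draft.seq[pos]
            assert table.inverse_lift(new) == pos

    def test_conservation_outside_replaced_spans(self, default_bundle):
        b = default_bundle
        patched, report = patch_all([b.draft], b.donors, b.anchors)
        spans = sorted(p["replaced_span"] for p in report.filled)
        pos = 0
        for start, end in spans:
            assert patched[0].seq[pos:start] == b.draft.seq[pos:start]
            pos = end
        # lengths are conserved here (donor spans replace equal-length spans)
        assert patched[0].seq[pos:] == b.draft.seq[pos:]
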