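"""Seeded ground-truth simulator.

Emulates the data regime of a repeat-rich plant chromosome end to
end: telomeric arrays at both ends, a centromere-like region of
tandem satellite blocks carrying cluster-diagnostic substitutions and
LTR-like interruptions, unique flanking sequence, a degraded draft
with planted N-gaps, donor contigs and anchor clones spanning each
gap, plus methylation and ChIP tracks over the satellite clusters.

Determinism: one root seed is split into named substreams (genome,
satellite, LTR, telomere, gaps, errors, anchors, reads, methylation,
ChIP), so adding a component never perturbs the draws of the others.
The same (config, seed) always yields a byte-identical bundle, and an
internal audit cross-checks every truth annotation against the
emitted sequences before anything is returned.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .satellite import CEN180_CONSENSUS
from .seqio import GenomicInterval, Sequence, reverse_complement, write_bed, write_fasta

_BASES = np.array(list("ACGT"))

_STREAMS = (
    "genome",
    "satellite",
    "ltr",
    "telomere",
    "gaps",
    "errors",
    "anchors",
    "reads",
    "methylation",
    "chip",
)


@dataclass(frozen=True)
class SatelliteSpec:
    consensus: str = CEN180_CONSENSUS
    clusters: int = 4
    copies_per_cluster: int = 100
    diagnostic_substitutions: int = 8
    per_copy_substitution_rate: float = 0.01


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    unique_segment_length: int = 30_000
    satellite: SatelliteSpec = field(default_factory=SatelliteSpec)
    ltr_count: int = 2
    ltr_length: int = 2_000
    telomere_unit: str = "CCCTAAA"
    telomere_copies_per_end: int = 300
    gap_count: int = 3
    gap_length_range: tuple[int, int] = (2_000, 4_000)
    anchor_length: int = 1_500
    anchor_distance_range: tuple[int, int] = (200, 800)
    donor_flank: int = 4_000
    assembly_error_rate: float = 0.0
    donor_inverted: Optional[tuple[bool, ...]] = None
    # draw anchors from inside the satellite arrays instead of the
    # unique gap flanks, to exercise the non-unique-placement rejection
    anchors_in_satellite: bool = False
    methylation_background: float = 0.6
    methylation_block: float = 0.85
    methylation_coverage: int = 30
    methylation_sites: int = 400
    chip_cluster_weights: tuple[float, ...] = (1.0, 1.0, 3.0, 1.0)
    chip_reads_per_sample: int = 5_000
    chip_read_length: int = 100

    def validate(self) -> None:
        sat = self.satellite
        for name, rate in (
            ("per_copy_substitution_rate", sat.per_copy_substitution_rate),
            ("assembly_error_rate", self.assembly_error_rate),
            ("methylation_background", self.methylation_background),
            ("methylation_block", self.methylation_block),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {rate}")
        if sat.clusters * sat.diagnostic_substitutions > len(sat.consensus):
            raise ValueError(
                "diagnostic sites exceed consensus length: clusters x sites "
                "must fit in the consensus"
            )
        if self.gap_count > 0:
            max_gap = self.gap_length_range[1]
            room = self.unique_segment_length
            need = self.gap_count // 2 + self.gap_count % 2
            span = max_gap + 2 * (
                self.anchor_distance_range[1] + self.anchor_length
            ) + 2_000
            if need * span > room:
                raise ValueError(
                    "gaps (with anchor room) do not fit the unique segments; "
                    "increase unique_segment_length or reduce gap_count"
                )
        if self.donor_inverted is not None and len(self.donor_inverted) != self.gap_count:
            raise ValueError("donor_inverted must have one flag per gap")
        if len(self.chip_cluster_weights) != sat.clusters:
            raise ValueError("chip_cluster_weights must have one weight per cluster")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TruthBundle:
    config: SimulationConfig
    truth_genome: Sequence
    draft: Sequence
    donors: list[Sequence]
    anchors: list[Sequence]
    monomer_truth: list[GenomicInterval]  # name = cluster label (1-based)
    cluster_blocks: list[GenomicInterval]  # name = cluster label
    gap_truth: list[GenomicInterval]
    telomere_truth: list[dict]
    satellite_region: GenomicInterval
    methylation_calls: list[tuple[str, int, str, bool]]
    methylation_site_truth: list[dict]
    chip_treatment: list[GenomicInterval]
    chip_control: list[GenomicInterval]
    manifest: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([self.truth_genome], outdir / "truth.fa")
        write_fasta([self.draft], outdir / "draft.fa")
        write_fasta(self.donors, outdir / "donors.fa")
        write_fasta(self.anchors, outdir / "anchors.fa")
        write_bed(self.monomer_truth, outdir / "monomers.truth.bed")
        write_bed(self.cluster_blocks, outdir / "cluster_blocks.truth.bed")
        write_bed(self.gap_truth, outdir / "gaps.truth.bed")
        write_bed(self.chip_treatment, outdir / "chip_treatment.bed")
        write_bed(self.chip_control, outdir / "chip_control.bed")
        with open(outdir / "methylation_calls.tsv", "w") as fh:
            for sid, pos, rid, m in self.methylation_calls:
                fh.write(f"{sid}\t{pos}\t{rid}\t{int(m)}\n")
        with open(outdir / "telomeres.truth.tsv", "w") as fh:
            fh.write("seq\tend\tstart\tstop\tunits\n")
            for t in self.telomere_truth:
                fh.write(
                    f"{t['seq']}\t{t['end']}\t{t['start']}\t{t['stop']}\t{t['units']}\n"
                )
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _cluster_variants(rng: np.random.Generator, spec: SatelliteSpec) -> list[str]:
    """Per-cluster consensus variants with disjoint diagnostic sites."""
    positions = rng.permutation(len(spec.consensus))
    variants = []
    for c in range(spec.clusters):
        sites = positions[
            c * spec.diagnostic_substitutions : (c + 1) * spec.diagnostic_substitutions
        ]
        arr = np.array(list(spec.consensus))
        for p in sites:
            choices = [b for b in "ACGT" if b != arr[p]]
            arr[p] = choices[rng.integers(0, 3)]
        variants.append("".join(arr))
    return variants


def simulate(config: SimulationConfig) -> TruthBundle:
    """Build a fully annotated truth bundle from (config, seed)."""
    config.validate()
    rngs = _rngs(config.seed)
    chrom_id = "chrSim"
    pieces: list[str] = []
    offset = 0
    monomers: list[GenomicInterval] = []
    blocks: list[GenomicInterval] = []
    telomeres: list[dict] = []

    def _append(s: str) -> int:
        nonlocal offset
        pieces.append(s)
        start = offset
        offset += len(s)
        return start

    # 5' telomere
    tel5 = config.telomere_unit * config.telomere_copies_per_end
    start = _append(tel5)
    telomeres.append(
        {
            "seq": chrom_id,
            "end": "5'",
            "start": start,
            "stop": start + len(tel5),
            "units": config.telomere_copies_per_end,
        }
    )
    # left unique segment
    _append(_random_dna(rngs["genome"], config.unique_segment_length))

    # satellite region: one block per cluster, LTRs inserted between copies
    sat = config.satellite
    variants = _cluster_variants(rngs["satellite"], sat)
    sat_start = offset
    total_copies = sat.clusters * sat.copies_per_cluster
    ltr_slots = (
        sorted(
            rngs["ltr"].choice(
                np.arange(1, total_copies), size=config.ltr_count, replace=False
            ).tolist()
        )
        if config.ltr_count
        else []
    )
    copy_counter = 0
    for c in range(sat.clusters):
        block_start = offset
        for _ in range(sat.copies_per_cluster):
            if copy_counter in ltr_slots:
                _append(_random_dna(rngs["ltr"], config.ltr_length))
            copy = _mutate(
                rngs["satellite"], variants[c], sat.per_copy_substitution_rate
            )
            mstart = _append(copy)
            monomers.append(
                GenomicInterval(
                    chrom_id, mstart, mstart + len(copy), "+", str(c + 1)
                )
            )
            copy_counter += 1
        blocks.append(
            GenomicInterval(chrom_id, block_start, offset, "+", str(c + 1))
        )
    sat_region = GenomicInterval(chrom_id, sat_start, offset)

    # right unique segment and 3' telomere
    _append(_random_dna(rngs["genome"], config.unique_segment_length))
    tel3 = reverse_complement(config.telomere_unit) * config.telomere_copies_per_end
    start = _append(tel3)
    telomeres.append(
        {
            "seq": chrom_id,
            "end": "3'",
            "start": start,
            "stop": start + len(tel3),
            "units": config.telomere_copies_per_end,
        }
    )
    genome_seq = "".join(pieces)
    truth = Sequence(chrom_id, genome_seq)

    # ---- gaps, anchors, donors -------------------------------------
    # Gaps are planted in the unique segments, far enough from the
    # segment boundaries to leave room for anchors and donor flanks.
    gap_rng = rngs["gaps"]
    anchor_rng = rngs["anchors"]
    left_u = (len(tel5), len(tel5) + config.unique_segment_length)
    right_u = (sat_region.end, sat_region.end + config.unique_segment_length)
    margin = (
        config.anchor_distance_range[1] + config.anchor_length + 1_000
    )
    gap_intervals: list[GenomicInterval] = []
    slots: list[tuple[int, int]] = []
    for seg_start, seg_end in (left_u, right_u):
        usable = seg_end - seg_start - 2 * margin
        slots.append((seg_start + margin, seg_end - margin))
    attempts = 0
    while len(gap_intervals) < config.gap_count:
        attempts += 1
        if attempts > 1000:
            raise ValueError("could not place gaps without overlap; config infeasible")
        seg = slots[len(gap_intervals) % len(slots)]
        glen = int(gap_rng.integers(*config.gap_length_range))
        gstart = int(gap_rng.integers(seg[0], seg[1] - glen))
        cand = GenomicInterval(chrom_id, gstart, gstart + glen)
        if all(
            cand.end + margin < g.start or g.end + margin < cand.start
            for g in gap_intervals
        ):
            gap_intervals.append(cand)
    gap_intervals.sort(key=lambda g: g.start)

    anchors: list[Sequence] = []
    donors: list[Sequence] = []
    inverted_flags = config.donor_inverted or tuple([False] * config.gap_count)
    for i, gap in enumerate(gap_intervals):
        dl = int(anchor_rng.integers(*config.anchor_distance_range))
        dr = int(anchor_rng.integers(*config.anchor_distance_range))
        if config.anchors_in_satellite:
            unit = len(sat.consensus)
            l_start = sat_region.start + (2 * i) * unit
            r_start = sat_region.start + (2 * i + 1) * unit
            l_end = l_start + config.anchor_length
            r_end = r_start + config.anchor_length
            anchors.append(Sequence(f"anchorL{i+1}", genome_seq[l_start:l_end]))
            anchors.append(Sequence(f"anchorR{i+1}", genome_seq[r_start:r_end]))
        else:
            l_end = gap.start - dl
            l_start = l_end - config.anchor_length
            r_start = gap.end + dr
            r_end = r_start + config.anchor_length
            anchors.append(Sequence(f"anchorL{i+1}", genome_seq[l_start:l_end]))
            anchors.append(Sequence(f"anchorR{i+1}", genome_seq[r_start:r_end]))
        d_start = max(0, gap.start - config.donor_flank)
        d_end = min(len(genome_seq), gap.end + config.donor_flank)
        dseq = genome_seq[d_start:d_end]
        if inverted_flags[i]:
            dseq = reverse_complement(dseq)
        donors.append(Sequence(f"donor{i+1}", dseq))

    # ---- draft: N-gaps plus optional substitution noise -------------
    err_rng = rngs["errors"]
    draft_chars = np.array(list(genome_seq))
    if config.assembly_error_rate > 0:
        hit = err_rng.random(len(draft_chars)) < config.assembly_error_rate
        for pos in np.flatnonzero(hit):
            choices = [b for b in "ACGT" if b != draft_chars[pos]]
            draft_chars[pos] = choices[err_rng.integers(0, 3)]
    for gap in gap_intervals:
        draft_chars[gap.start : gap.end] = "N"
    draft = Sequence(chrom_id, "".join(draft_chars))

    # ---- methylation track ------------------------------------------
    meth_rng = rngs["methylation"]
    calls: list[tuple[str, int, str, bool]] = []
    site_truth: list[dict] = []
    positions = np.sort(
        meth_rng.choice(len(genome_seq), size=config.methylation_sites, replace=False)
    )
    for pos in positions.tolist():
        in_block = sat_region.start <= pos < sat_region.end
        true_f = config.methylation_block if in_block else config.methylation_background
        cov = config.methylation_coverage
        meth = meth_rng.binomial(1, true_f, size=cov)
        for r in range(cov):
            calls.append((chrom_id, int(pos), f"r{pos}_{r}", bool(meth[r])))
        site_truth.append(
            {"position": int(pos), "true_frequency": true_f, "in_block": in_block}
        )

    # ---- ChIP reads --------------------------------------------------
    # Genome-wide libraries: control is uniform per bp; treatment
    # up-weights each cluster block by its planted factor. With the
    # blocks a minor share of the genome, the library-size-normalized
    # enrichment ratio of block i approaches its weight.
    chip_rng = rngs["chip"]
    glen = len(genome_seq)
    weights = np.array(config.chip_cluster_weights, dtype=float)
    block_lens = np.array([b.length for b in blocks], dtype=float)
    # sampling domains: each block, plus the rest of the genome as one
    # background domain (reads placed uniformly inside their domain)
    bg_len = glen - block_lens.sum()
    t_mass = np.append(weights * block_lens, bg_len)
    c_mass = np.append(block_lens, bg_len)
    chip_t: list[GenomicInterval] = []
    chip_c: list[GenomicInterval] = []
    # background = complement of the blocks, as (start, end) pieces
    bg_pieces: list[tuple[int, int]] = []
    pos = 0
    for b in blocks:
        if b.start > pos:
            bg_pieces.append((pos, b.start))
        pos = b.end
    if pos < glen:
        bg_pieces.append((pos, glen))
    bg_starts = np.array([p[0] for p in bg_pieces])
    bg_lens = np.array([p[1] - p[0] for p in bg_pieces], dtype=float)
    for mass, out in ((t_mass, chip_t), (c_mass, chip_c)):
        probs = mass / mass.sum()
        choices = chip_rng.choice(len(mass), size=config.chip_reads_per_sample, p=probs)
        for d_idx in choices.tolist():
            if d_idx < len(blocks):
                b = blocks[d_idx]
                lo, hi = b.start, max(b.start + 1, b.end - config.chip_read_length)
            else:
                piece = chip_rng.choice(len(bg_pieces), p=bg_lens / bg_lens.sum())
                lo = int(bg_starts[piece])
                hi = max(lo + 1, lo + int(bg_lens[piece]) - config.chip_read_length)
            s = int(chip_rng.integers(lo, hi))
            out.append(
                GenomicInterval(chrom_id, s, s + config.chip_read_length, "+")
            )

    manifest = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "genome_length": len(genome_seq),
        "monomer_count": len(monomers),
        "gap_count": len(gap_intervals),
        "toolkit": "anchorfill-0.1.0",
    }
    bundle = TruthBundle(
        config=config,
        truth_genome=truth,
        draft=draft,
        donors=donors,
        anchors=anchors,
        monomer_truth=monomers,
        cluster_blocks=blocks,
        gap_truth=gap_intervals,
        telomere_truth=telomeres,
        satellite_region=sat_region,
        methylation_calls=calls,
        methylation_site_truth=site_truth,
        chip_treatment=chip_t,
        chip_control=chip_c,
        manifest=manifest,
    )
    _audit(bundle)
    return bundle


def _audit(bundle: TruthBundle) -> None:
    """Internal consistency check before the bundle is released."""
    g = bundle.truth_genome.seq
    cfg = bundle.config
    for gap in bundle.gap_truth:
        if set(bundle.draft.seq[gap.start : gap.end]) != {"N"}:
            raise AssertionError("planted gap is not an N-run in the draft")
    for m in bundle.monomer_truth:
        if not m.length:
            raise AssertionError("empty monomer interval")
    for t in bundle.telomere_truth:
        unit = (
            cfg.telomere_unit
            if t["end"] == "5'"
            else reverse_complement(cfg.telomere_unit)
        )
        if g[t["start"] : t["start"] + len(unit)] != unit:
            raise AssertionError("telomere truth does not match the genome")
    # monomer sequences re-extracted must match their cluster variant length
    for m in bundle.monomer_truth[:10]:
        if len(g[m.start : m.end]) != m.length:
            raise AssertionError("monomer interval out of bounds")


def degrade(
    truth_genome: Sequence,
    gap_intervals: list[GenomicInterval],
    error_rate: float,
    seed: int,
) -> Sequence:
    """Plant N-runs and substitution noise into a copy of the genome."""
    ivs = sorted(gap_intervals, key=lambda g: g.start)
    for a, b in zip(ivs, ivs[1:]):
        if b.start < a.end:
            raise ValueError("overlapping planted gaps")
    rng = np.random.default_rng(seed)
    chars = np.array(list(truth_genome.seq))
    if error_rate > 0:
        in_gap = np.zeros(len(chars), dtype=bool)
        for gap in ivs:
            in_gap[gap.start : gap.end] = True
        hit = (rng.random(len(chars)) < error_rate) & ~in_gap
        for pos in np.flatnonzero(hit):
            choices = [b for b in "ACGT" if b != chars[pos]]
            chars[pos] = choices[rng.integers(0, 3)]
    for gap in ivs:
        chars[gap.start : gap.end] = "N"
    return Sequence(truth_genome.id, "".join(chars))
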