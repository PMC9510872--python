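# anchorfill

Assembly-finishing and centromere-architecture toolkit for
telomere-to-telomere (T2T) genome projects, aimed at the finishing
stage of a repeat-rich plant chromosome: closing the last scaffold
gaps from an orthogonal contig set, validating the result against
independently sequenced clones, scoring consensus quality from
k-mers, and dissecting the centromeric satellite arrays that made the
region hard to assemble in the first place.

## What it computes

**Anchor-guided gap filling.** A draft assembly carries N-gaps,
typically in centromeres. For each gap, `anchorfill` looks for two
anchor sequences (BAC-like clones) that align at very high identity
(default > 99.9%) both to the draft — flanking the gap — and to a
single donor contig (e.g., a HiFi contig), in the same relative order
and orientation. The donor sequence between the anchors then replaces
the draft span (or the whole contig, in whole-contig mode), with a
liftover table mapping old to new coordinates. Anchors with ambiguous
placements (a second hit ≥ 98% identity covering ≥ 50% of the anchor)
are rejected, so satellite-internal anchors cannot misplace a patch.

**Clone validation.** A clone is *resolved* when ≥ 99.5% of its
length aligns to a single contig (merged hit intervals on the clone
axis, so tandem multi-hits never double-count). The resolution rate
is the percentage of resolved clones; per-clone identities are
summarized length-weighted and unweighted.

**k-mer consensus quality.** With T total assembly k-mer instances
and B of them absent from the read set, the per-base error rate is

    E = 1 − (1 − B/T)^(1/k),   QV = −10·log₁₀(E),
    accuracy% = 100 − 10^(QV/−10) × 100

and k-mer completeness is the share of reliable read k-mers
(multiplicity ≥ 2) present in the assembly. Default k = 21, canonical
k-mers, N-containing k-mers skipped.

**Satellite architecture.** Monomers of a tandem satellite (presets:
the 178-bp centromeric CEN180 unit, length window 165–185 bp; 5S rDNA,
490–510 bp) are detected on both strands at ≥ 90% consensus coverage,
projected onto consensus columns, and clustered with a per-column
multinomial mixture over {A,C,G,T,−} fitted by EM. The cluster count
K\* is chosen by the BIC *inflection*: the K maximizing the discrete
second difference BIC(K−1) − 2·BIC(K) + BIC(K+1) over K = 2…10.
Windowed pairwise-identity matrices (default window 5 kb) expose
array-scale homogeneity. Telomeric arrays (unit CCCTAAA/TTTAGGG) are
detected at sequence ends with a purity-tolerant scan, and novel
regions are extracted as the complement of alignment coverage.

**Epigenomic summaries.** Per-read methylation calls are aggregated
to per-site frequencies and summarized per region (mean frequency and
the fraction of sites with frequency > 0.8). ChIP enrichment assigns
reads to satellite-cluster footprints by midpoint, normalizes to
counts-per-million over each library, and reports the
treatment/control ratio with a 0.5-CPM pseudocount.

**Simulator.** A seeded generator builds ground-truthed bundles —
telomeres, a centromere-like region of satellite blocks with
cluster-diagnostic substitutions and LTR-like interruptions, unique
flanks, a gapped draft, donors, anchors, methylation and ChIP
tracks — so every pipeline stage is testable offline with known truth.

## Worked example

```sh
anchorfill simulate --seed 7 --out sim
anchorfill patch --draft sim/draft.fa --donors sim/donors.fa \
    --anchors sim/anchors.fa --out-prefix filled
anchorfill qv --assembly filled.patched.fa --reads sim/truth.fa --out-prefix qv
anchorfill satellites --genome sim/truth.fa --seed 7 --out-prefix sat
```

prints (stderr):

```
bundle written to sim
filled 3 gap(s); 0 remaining
QV 99.00  accuracy 100.000000%  completeness 100.00%
395 monomers, K*=4
```

The simulated draft carried three planted centromere-scale gaps; all
three were closed from the donor contigs via flanking anchors
(`filled.patches.tsv` lists each replaced span with its anchor
provenance, `filled.remaining_gaps.bed` is empty). Because the
patched assembly is byte-identical to the simulated truth genome, no
assembly k-mer is unsupported by the read set: B = 0, so the QV is
reported at its cap (99, flagged `qv_capped`) rather than infinity,
and completeness is 100%. The satellite scan finds the ~400 planted
CEN180 monomers and the BIC inflection selects K\* = 4, the planted
number of monomer clusters (`sat.bic.tsv` holds the full BIC curve,
`sat.monomers.bed` the per-monomer cluster labels).

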