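# Methods

This note documents the models and procedures behind `anchorfill`,
the defaults they ship with, and the choices made where the design
was genuinely open.

## Alignment contract

All anchoring, clone validation and monomer detection go through one
local-alignment contract (`align.align_local`): exact k-mer seeds
(k = 15, query sampled every 5 bp) are matched against a target
index, clustered by diagonal (band 50 bp), and each cluster's window
is aligned with edlib in infix mode to obtain a full `=`/`X`/`I`/`D`
CIGAR. Because infix alignment must consume the whole query, the
CIGAR is then trimmed to its best-scoring contiguous run of
operations (Kadane's maximum-subarray at operation granularity) under
the toolkit scoring scheme — match +1, mismatch −2, gap open −4, gap
extend −1 — which restores local semantics: query ends that do not
belong to the alignment are clipped instead of dragged in.

*Identity* is column-inclusive ("BLAST identity"): matched columns
divided by all alignment columns, counting inserted and deleted bases
in the denominator. This is the strictest common convention and makes
a 99.9% anchor gate meaningful for gap-containing alignments. Every
hit's identity is recomputable from its CIGAR; this invariant is
tested. Ties among equal-score hits break to the leftmost target
start, then the + strand.

Known consequence of delegating extension to an edit-distance
aligner: among co-optimal unit-cost paths edlib may represent two
adjacent substitutions as an insertion plus a deletion, which scores
slightly lower under the affine scheme than the substitution path.
The identity is unaffected at the reported precision; the test suite
checks best-hit identity against a quadratic Gotoh DP oracle within
0.002 and requires the score to sit within a small band below the DP
optimum.

Tandem repeats spawn one seed cluster per phase shift. Monomer
detection needs all of them (one per copy); clone validation and
heatmap windows only need coverage or a best hit, so those callers
cap the number of extended clusters (25 and 5 respectively, richest
seed clusters first).

## Gap patching

Gaps are maximal N-runs ≥ 10 bp (shorter runs are treated as
incidental ambiguity, not scaffolding gaps). For each gap the
selector collects anchors whose best draft hit exceeds the identity
gate (default 0.999, strict), covers ≥ 90% of the anchor, and is
uniquely placed — any second placement at ≥ 98% identity covering
≥ 50% of the anchor disqualifies it. Among concordant pairs (same
relative order and orientation on draft and donor, both donor hits on
one contig) the pair minimizing the summed gap-to-anchor distance
wins. Span mode replaces the draft between the inner anchor
boundaries with the corresponding donor span (reverse-complemented
for inverted donors); whole-contig mode substitutes the entire donor
between the outer anchor boundaries. Overlapping candidate plans are
resolved in favour of the higher combined anchor identity, and a
liftover table (segment + offset; replaced segments map to nothing)
accompanies every edit. Patching applies right-to-left per scaffold
so planned coordinates stay valid.

The distance-minimizing, same-contig pairing rule and the coverage
requirement are this package's choices; the anchoring idea itself
assumes anchors are long enough (default simulated length 1.5 kb)
to be unique in non-repetitive flanking sequence.

## Clone validation

Aligned bases are counted on the clone axis after merging overlapping
hit intervals per contig — tandem multi-hits cannot inflate coverage —
and the verdict comes from the best single contig with an inclusive
threshold (aligned fraction ≥ 0.995). The resolution rate is rounded
half-up to 2 decimals. Mean identity across clones is reported both
length-weighted (default) and unweighted, since either convention is
defensible.

## k-mer consensus quality

Canonical k-mers (lexicographic minimum of k-mer and reverse
complement; k odd to avoid self-complementary ambiguity, default 21,
maximum 31 so codes fit 64-bit integers) are counted with a
vectorized encoder; windows containing N are skipped. The error model
treats every assembly k-mer absent from the reads as evidence of a
consensus error that corrupts up to k overlapping k-mers:
E = 1 − (1 − B/T)^(1/k), QV = −10·log₁₀E. When B = 0 the QV is
reported at a cap (99) with an explicit flag rather than infinity.
Accuracy is 100 − 10^(QV/−10)·100, printed at 6 decimals with
half-up rounding. Completeness excludes read k-mers below a
reliability floor (default multiplicity 2) as presumed sequencing
errors. The assumptions — reads deep enough that true genomic k-mers
are all observed, errors rare enough that error k-mers are mostly
singletons — are the standard ones for k-mer-based QV.

## Satellite monomers and clustering

Monomer detection aligns the consensus against both genome strands,
keeps hits covering ≥ 90% of the consensus, resolves overlaps
greedily by score (a hit overlapping a retained hit by > 10% of its
own length is dropped), and filters on genomic hit length (CEN180:
165–185 bp; 5S: 490–510 bp). Minus-strand monomers are
reverse-complemented into consensus orientation.

Instead of a progressive multiple alignment, each monomer is aligned
pairwise to the consensus (edlib, global) and projected onto
consensus columns: deletions become gap symbols, insertions are
collapsed (they have no consensus column). For near-fixed-length
satellite monomers this consensus-anchored projection is accurate and
O(n); rows aligning below 0.5 identity are excluded with a warning.

Clustering fits a per-column independent multinomial mixture over
{A,C,G,T,−} by EM: 10 random-responsibility restarts, ≤ 200
iterations, relative log-likelihood tolerance 10⁻⁶, Laplace smoothing
α = 0.1 on the column multinomials, all driven by one seeded
generator (same seed ⇒ identical result). BIC = −2·logL + p·ln n with
p = (K−1) + K·C·(S−1) free parameters (C consensus columns, S = 5
symbols). K\* maximizes the discrete second difference of the BIC
curve — the "elbow" — rather than the BIC minimum, which for this
over-parameterized likelihood tends to undershoot visually distinct
cluster structure. Because a second difference needs both neighbours,
a single-component fit (closed form, no EM) extends the curve below
the smallest candidate K, so K = 2 is selectable. Identical rows
short-circuit to K\* = min(K), flagged degenerate. The mixture is a
transparent surrogate for likelihood-based satellite classification;
it ignores column dependence and phylogenetic structure, which is
acceptable for diagnostic-site-driven cluster recovery but not a
substitute for evolutionary modelling.

Identity heatmaps tile a region into non-overlapping windows
(default 5 kb) and report the best local-alignment identity per
window pair, 0 when no alignment covers ≥ 50% of a window at ≥ 0.5
identity; the diagonal is 1 by definition.

## Telomeres and novel regions

Telomere detection searches the unit (CCCTAAA) at 5′ ends and its
reverse complement at 3′ ends, within 1 kb of the end, and extends a
two-state scan that counts exact unit copies and tolerates
interruptions while overall purity stays ≥ 0.8; arrays need ≥ 10
units. A regex for exact runs would undercount the degenerate copies
real telomeres accumulate. Novel regions are the per-sequence
complement of merged alignment coverage; identity/length filtering of
the alignments (defaults 95% / 10 kb) happens upstream, so covered
and novel intervals always partition each sequence exactly.

## Epigenomic summaries

Methylation calls (position, read, binary state) are aggregated per
site; duplicate (position, read) pairs keep the first call with a
warning. Region summaries report the mean site frequency and the
fraction of sites strictly above the threshold (default 0.8).

ChIP reads are assigned to cluster regions by midpoint (unambiguous
for boundary-spanning reads) and normalized to counts-per-million of
the *whole library* — all reads supplied for that sample, inside or
outside the analyzed regions. This library-size normalization is
deliberate: normalizing within the analyzed regions alone forces the
control-weighted mean of enrichment ratios to 1 and caps a planted
3-fold preference at 2.0 for four equal clusters, making the planted
factor unrecoverable in principle. With genome-wide libraries in
which the clusters are a minor share, the enrichment ratio
(treatment CPM + 0.5) / (control CPM + 0.5) approaches the true
preference factor. The pseudocount keeps empty controls finite and is
disclosed in the output.

## Simulator: what it does and does not emulate

The generator assembles, left to right: a 5′ telomere (300 exact
units), 30 kb of unique sequence, four satellite blocks of 100
monomer copies each, 30 kb of unique sequence, and a 3′ telomere, for
a ~139 kb "chromosome". Cluster structure comes from 8 diagnostic
substitutions per cluster at disjoint consensus positions plus 1%
per-copy random substitutions; two 2-kb random insertions mimic LTR
interruptions. The draft carries three planted N-gaps (2–4 kb) in the
unique segments with 1.5-kb anchors at 200–800 bp from each gap edge
and donors spanning gap ± 4 kb; an option places anchors inside the
satellite arrays instead, to exercise the non-uniqueness rejection
path. Methylation is binomially sampled at 30× over 400 sites with
frequency 0.85 inside the satellite region and 0.6 outside; ChIP
libraries are genome-wide (default 5 000 reads of 100 bp; the
ChIP-recovery analyses use 10–50 k reads with 30-copy blocks so the
blocks are a minor library share) with per-cluster weights
(1, 1, 3, 1). One root seed is split into named substreams per
component, so adding a component never perturbs the others; an
internal audit cross-checks truth annotations against the emitted
sequences before a bundle is released.

These sizes are deliberately desk-scale: large enough that k-mer
statistics, anchor uniqueness and cluster recovery behave as they do
at genome scale, small enough that the full suite runs in well under
a minute per bundle. What the simulator does *not* emulate: read-level
sequencing error profiles (reads enter as k-mer sets or interval
tables), higher-order repeat structure, satellite homogenization
gradients, heterozygosity, and real chromatin fragment-length
distributions. Passing tests therefore demonstrate correctness of the
computations and recoverability of planted structure, not performance
on real centromeres, where divergent monomers, nested transposons and
segmental duplications make anchoring and monomer resolution harder.

## Degenerate inputs and numerical conventions

Absent alignments are empty lists, never errors; a gap with no
qualifying anchor pair is reported unfilled; a clone with no hits gets
aligned fraction 0. Percentages print with half-up rounding (2
decimals for rates, 6 for accuracy). All module boundaries exchange
0-based half-open coordinates; BED emission preserves them. FASTA
input is uppercased and non-ACGTN codes become N with a warning,
keeping every downstream alphabet closed. Reported problem sizes in
the acceptance summary are the sizes actually used at run time.
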