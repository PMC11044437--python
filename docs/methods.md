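# Methods

This note documents the models, conventions and design choices behind
`pangview`, in the order data flows through the package.

## Graph model and I/O

A variation graph is a bidirected sequence graph: nodes carry non-empty
uppercase DNA over {A, C, G, T, N}; edges connect oriented node ends; paths
are named, ordered, oriented walks. Path names follow the `GENOME.chr`
convention so region strings resolve directly; the genome of a path is the
name up to its last dot. GFA v1 is the sole interchange dialect (S/L/P
lines plus optional W walks, which become paths named `sample.seqid`, with
a non-zero haplotype index folded in as `sample#hap.seqid`). Only
blunt-ended graphs are accepted — an L line with a non-`0M` overlap is an
error — because both mainstream pangenome builders emit blunt graphs after
conversion, and overlapped links would break the additivity of path
coordinates that everything downstream relies on.

Writing is deterministic (nodes and paths lexicographic); links implied by
path adjacency but missing from the edge set are emitted so output is
always a valid strict graph. Graphs whose edge sets already contain the
implied links round-trip byte-identically. Graphs are immutable after
load; per-path cumulative-start and node→step indexes are built lazily and
cached on that assumption.

Two loading modes exist because builder dialects differ on whether every
path adjacency has an explicit L line: lenient (default) accepts
path-implied adjacencies, strict validation reports them as findings and
`read_gfa(strict=True)` refuses them.

## Annotations and binding

GFF3 is the sole annotation dialect. Features keep GFF3 semantics
(1-based inclusive, forward-strand coordinates); internally all arithmetic
is 0-based half-open, converted at the boundary. The gene hierarchy is
resolved via ID/Parent; exon/CDS features with unresolvable parents are
retained, flagged as orphans, and wrapped in synthetic single-exon gene
containers so comparison still sees them. *Binding* resolves seqids to
paths (`genome.seqid` by convention, or an explicit rename map for
graphs with other naming schemes) and never touches coordinates; it is
idempotent. A feature ending beyond its path's length is rejected at
binding time.

Gene *structure* is compared on exon features by default, with CDS behind
a flag: the rendered bars are exons, and structure comparison should see
exactly what the picture shows. A gene's representative transcript is its
lexicographically first transcript id — deterministic and cheap; callers
with transcript-level needs can walk the hierarchy themselves. Minus-strand
features stay in forward-strand coordinates; strand only matters for the
frame analysis, not for projection.

## Coordinate projection

`linear_to_graph` maps a path interval to node segments in path order. On
a reverse step, traversal offset `i` corresponds to forward-node offset
`len − 1 − i`, so segments always report forward-node offsets plus the
traversal orientation; this makes splice-site comparison
orientation-independent. `graph_to_linear` returns one position per
traversal (loops give several, skipped nodes none). Feature boundary
coordinates are the (node, forward offset) of the first and last base.

Region subgraphs take the anchor's traversed nodes whole (no node
splitting): the viewer semantics are whole-node, and the anchor's exact
interval is preserved instead through entry/exit offsets on its clipped
run, which reconstructs the requested substring exactly. Consequence: the
anchor's clipped representation is a single run spanning the query
interval; other paths are clipped to maximal runs by node-set membership
only — no alignment is computed, so a path "appears" in a region exactly
when it shares nodes with the anchor there. Per-path region spans
(`path_span_in_region`) generally differ in length across genomes, because
indels make the shared graph coordinates unevenly distributed along each
genome; nothing in the package assumes equal spans.

## PAV and gSV calling

The presence matrix counts node traversals per genome over the clipped
runs (loops count multiply; multiple paths of one genome sum). Grouping by
a node splits region genomes into traversing (count ≥ 1) and skipping
(count 0); genomes absent from the region entirely are reported as
*unplaced*, not as skippers — only tracks aligned in the region are
grouped.

`compare_gene` projects the reference gene's exons and classifies every
other genome in this order:

1. if the genome annotates a gene whose projected exons share graph
   positions with the reference projection (largest shared base count
   wins), splice sites are compared as exact (node, forward-offset)
   equality of the per-exon boundary lists: all equal →
   `identical_structure`; same exon count, any boundary differing →
   `boundary_shift`; exon count differing → `element_pav`;
2. otherwise the *coverage* fraction — the share of reference **exonic**
   projected positions lying on nodes the genome traverses — decides
   `absent_annotation` (≥ threshold, default 0.8) versus `absent_sequence`
   (below). Coverage is exonic rather than whole-gene-span because
   absence in this model is the absence of the drawn structure elements,
   and intron retention should not mask an exon-level loss.

Exact boundary equality (tolerance 0) is deliberate: the claim the package
supports is splice-site *identity* on the graph, not near-identity. The
threshold is exposed because no principled universal constant exists;
node-skip grouping remains available as the assumption-free alternative.

The coding indel scan aligns the two genomes' node walks through the gene
region with a longest-matching-subsequence diff on node ids. Runs present
in exactly one walk are indels; balanced replacement bubbles (equal
lengths both sides, e.g. SNP bubbles) are substitutions and excluded;
unbalanced replacements contribute their net length. Indels overlapping
the reference CDS (exons when no CDS is annotated) are reported with
`frame_preserving` iff length ≡ 0 (mod 3). The scan slices the other
genome's *raw* walk between its first and last visit of region nodes —
clipped runs would hide exactly the private bubble nodes the scan exists
to find.

The sequence locator is exact-match only: k-mer seeding (default k = 16)
with full verification, both strands, per path sequence. Gapped alignment
is out of scope; the `gaps` field of a hit is always 0 and exists for
schema compatibility with gapped-search reports.

## Rank-sum association

`rank_sum_test` uses midranks, U = R₁ − n₁(n₁+1)/2, the exact null
distribution when min(n₁, n₂) ≤ 10 without ties, and otherwise the normal
approximation with tie-corrected variance and 0.5 continuity correction
(ties always force the approximation; exact-with-ties enumeration is not
implemented). A fully constant pooled sample returns p = 1 by
exchangeability. The p-value computation is delegated to
`scipy.stats.mannwhitneyu` under exactly this branch rule; the test suite
checks the exact branch against an independent brute-force enumeration
over all rank assignments, exhaustively for n₁, n₂ ≤ 6. The
continuity-corrected approximation tracks the exact p within ~3% relative
error outside the deep tail (exact p ≥ 0.05) at n = 8 per group; in the
deep tail its relative error grows, which is inherent to the
approximation, so small-sample callers get the exact branch by default.
Sidedness defaults to two-sided. `associate_phenotype` drops genomes
without phenotype values (logged) and refuses degenerate groupings.

## Tube-map layout and rendering

Layout is deterministic. Columns: anchor nodes ranked by first occurrence
along the anchor path; off-anchor nodes at (minimum rank of their
within-path predecessors) + 0.5, with a backward pass for runs that start
off-anchor, ties broken lexicographically. Lanes: input path order, anchor
first. Crossing minimisation is not attempted. Node widths: full mode
`px_per_base × length`; compressed mode
`max(compressed_min_px, compressed_log_scale × log₁₀(length + 1))` —
a stated substitute for interactive viewers' undocumented compression,
chosen so long nodes stay readable while short nodes keep a legible floor.
Every projected feature segment becomes one bar rectangle placed inside
its node proportionally to its forward offsets (rescaled to the compressed
width in compressed mode). Bar base-pair lengths are invariant under mode
switching; only pixel widths change — which is why a shorter exon can
legitimately render wider than a longer one in compressed mode when the
shorter one spans width-floored small nodes.

Repeated traversals of a node (loops) revisit the same x-extent; nodes are
never duplicated. Rendering is a pure function of (layout, options):
stable element ordering and ids, byte-identical output on identical input.
A track with no projected features carries zero bars, so bar absence reads
as feature absence. The default palette is nine distinguishable light
colors, cycling beyond nine tracks; the inverted coloration grays the
tracks and colors the exon bars instead. Base letters render only in full
mode with `show_text` and `px_per_base ≥ 8` (legibility floor).

The junction report groups feature boundary coordinates; two genomes'
exon edges fall in one group exactly when their splice sites are identical
on the graph, which is the formal version of the visual
"junctions align" reading of a tube map.

## Synthetic pangenomes and ground truth

The generator emulates a pangenome built from one base chromosome plus
non-overlapping SNPs, insertions and deletions, each carried by a subset
of genomes. Non-overlap is enforced so the graph can be built *directly*:
the base is cut at variant breakpoints, giving each deletion exactly one
skippable node, each SNP a two-node bubble, each insertion one private
node — a graph constructor, not a graph-builder reimplementation. One RNG,
mandatory seed, byte-identical outputs per seed.

Defaults for random simulation: base 10 kb, 10 genomes, SNPs 2×10⁻³ per
base, insertions and deletions 2×10⁻⁴ each with lengths 1–30 — a
polymorphism density giving a bubble every few hundred bases, typical of
a diverse crop panel at small scale; genes of 1–5 exons (60–300 bp) are
planted along the base. Variant counts are Poisson; carrier frequency per
variant is uniform on (0.1, 0.9). Insertions are kept off exact exon
boundaries so annotation lifting is unambiguous.

Annotations are lifted per genome: positions shift by carried insertions
and deletions; exons fully covered by a carried deletion are dropped;
exons whose boundary bases are deleted are truncated. The ground-truth
gene fate mirrors the caller's semantics exactly: `absent` iff no exon
survives lifting; `structurally_variant` iff an exon is dropped or a
deletion removes an exon boundary base; else `present_identical`. Interior
exon indels and substitutions leave boundary graph coordinates unchanged
and are therefore `present_identical` — structure is splice sites, not
sequence. This rule makes truth and comparison provably commensurable: a
deletion-fraction rule was considered and rejected because it disagrees
with structure-first classification whenever a partial gene survives
annotation.

Fixed scenarios: the five-genome demo (exact geometry chosen so the
compressed-mode bar inversion holds under default render options); the
long-deletion scenario (a two-exon gene wholly inside a 382 bp deletion
carried by the designated first half of 40 genomes, plus background SNPs,
with a phenotype model whose causal carriers are the deletion carriers,
baseline 100, effect expressed in noise-SD units); and the
private-insertion scenario (a 1,345 bp insertion carried by 16 of 113
genomes). `random_graph` generates small unconstrained graphs with
reverse steps and loops for property-testing the coordinate machinery —
something the bubble-only simulator cannot exercise.

What the generator does **not** emulate: alignment artifacts and loop
normalization differences between real graph builders, overlapping or
nested variants, rearrangements/inversions (paths are all-forward),
sequencing or annotation error, and realistic mutation-rate or coalescent
structure. Passing tests therefore certify the coordinate algebra,
calling logic and rendering semantics — not robustness to messy real
graphs, which should be validated on builder output directly.

## Problem sizes and numerical choices

The shipped analyses use deliberately small instances: 1,000 random
triples for coordinate round trips, 200 features for projection
partitioning, 1,000 phenotype replicates for power and null calibration
(binomial SE ≈ 0.7% at α = 0.05, tight enough for the [0.03, 0.07]
calibration band), 10,000 replicates for the suite's type-I check, and the
113-genome insertion scenario at 4 kb base length. These sizes make every
result reproducible in seconds on one core while leaving the measured
quantities (recovery rates, power, calibration) effectively unchanged at
larger sizes. Floating-point comparisons in layout allow 10⁻⁹ slack for
bar-in-node containment; everything else is exact integer or string
equality. Degenerate inputs are first-class: empty regions, empty
annotation sets, constant phenotype vectors, single-genome groups and
palindromic locate queries all have defined behavior and tests.

## Known limitations

* In-memory only; no disk-backed graph index. Whole-genome graphs of real
  113-genome panels need chromosome-level chopping before loading.
* Exact-match locating only — a diverged homolog will not be found.
* The anchor defines the node set: variation private to *other* genomes
  within a region (e.g. their insertion alleles) is not part of the
  subgraph unless the query is re-anchored on such a genome. This mirrors
  the anchored-view semantics but differs from an all-alleles view.
* Lane order is input order; no crossing minimisation, so dense regions
  with many paths can be visually busy.
* Exact-with-ties rank-sum enumeration is not implemented; tied data get
  the corrected normal approximation regardless of sample size.
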