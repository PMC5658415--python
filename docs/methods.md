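# Methods

## Problem and model

The package detects inversions — reference intervals whose sequence appears
reverse-complemented in a sample genome — from whole-genome alignments of
per-strain assemblies against a reference, and asks whether large
inversions are enriched in a designated region (a region of suppressed
recombination on a fungal mating-type chromosome).  Detection works on
alignment *coordinate tables* only: an inversion manifests as reverse-
orientation segments between forward ones, regardless of whether the whole
pattern lies in one contig (complete assembly) or is spread over contigs
that abut on the reference in opposite directions (fragmented assembly).

Counting rules treat an inversion shared by several strains, or a cluster
of mutually overlapping inversions, as a single mutational event; the
enrichment statistic is a per-base-pair event rate compared between the
region and the rest of the genome under a uniform-placement null, tested
with the one-sided exact binomial tail.

## Alignment (anchor_align)

Seeding uses k-mers that occur exactly once in the reference, canonicalized
over both strands (default k = 21, odd so a k-mer never equals its own
reverse complement).  Exactly abutting seeds merge into maximal exact-match
anchors; anchors are chained greedily per (chromosome, orientation) in
reference order, breaking when the reference or query gap exceeds
`max_gap` (default 2,000 bp) or query order contradicts the orientation,
and chains below `min_cluster` (default 200) anchored bases are dropped.
These defaults mirror the cluster/break settings commonly used with
`nucmer` for fungal genome comparisons.  Unique-k-mer seeding suppresses
repeats by construction; there is no gapped extension, and segment identity
is reported as anchored bases over reference span.  Tie-breaks (equal
reference start) prefer longer anchors, then smaller coordinates, making
the output fully deterministic.

Block boundaries can jitter by 1–2 bp where a flanking base coincidentally
matches the first base beyond a breakpoint; the scanner's adjacency
tolerance absorbs this.

## Scanning (inv_scan)

Segments adjacent on the reference (gap within ± the adjacency tolerance,
default 5,000 bp) with opposite orientations yield breakpoint signals:
`F|R` at the left junction, `R|F` at the right.  The tolerance allows
small unaligned or repeat-rich stretches at junctions; the flanking
forward segment must span at least `min_flank` (default 1,000 bp, the
size of the smallest inversions considered).  When several contig pairs
support one junction, the pair with the longest combined flanks wins
(deterministic tie-break by contig id).

Pairing: each `F|R` at b₁ (processed innermost-first) takes the farthest
following `R|F` at b₂ such that (b₁, b₂] is covered by reverse segments
with no uncovered gap above the tolerance — the reversed run is maximal,
so the call spans the whole inverted block [b₁+1, b₂] and its size is
b₂ − b₁.  Calls below 1 kbp are not emitted.  Signals that cannot be
paired are reported as `unpaired` but never become events, implementing
the rule that both breakpoints must be identified.  A repeat screen drops
any signal whose flanking segment has an alternative alignment elsewhere
covering ≥ 80% of the same contig interval — the automated counterpart of
manually rejecting junctions caused by repetitive misalignment.

The junction patterns are expressed in absolute reference orientation.  A
contig stored fully reverse-complemented by an assembler inverts its
pattern; contigs aligning entirely inside an inversion are inherently
strand-ambiguous.  The simulator therefore shuffles contig order but keeps
contigs on their original strand; real-data use would normalize contig
strand by majority alignment first.  This is a known limitation, shared
with any coordinate-table-level scanner.

## Consolidation (consolidate)

Paired calls on one chromosome cluster by any-overlap (≥ 1 bp) connected
components; the event interval is the union envelope.  One mechanism
yields both counting rules (shared inversions once, overlapping clusters
once).  Filters: events < 1 kbp are dropped; events strictly larger than
100 kbp require two distinct evidence-type tags (tags ride on strain
metadata — `illumina`, `pacbio`, `optical`, `pcr_sanger` — wet-lab
verification is represented as a tag an operator attaches, not simulated);
events of at most 100 kbp require two carrier strains (any two strains; a
within-mating-type restriction was considered and not adopted, as the
cross-strain reading is the weaker and safer requirement).  The 100 kbp
boundary value itself classifies as small.  Fixation: per lineage, an
event is fixed within a mating type iff its carriers are exactly all
sampled strains of one mating type and none of the other.

## Enrichment (enrich)

Events are assigned to the region by integer midpoint ⌊(start+end)/2⌋ with
inclusive bounds — unambiguous for straddling events and consistent with
per-bp rate logic.  With counts k_in, k_out and lengths L_in, L_out, the
test statistic is P(X ≥ k_in) for X ~ Binomial(k_in+k_out, L_in/(L_in+L_out)),
the uniform-placement null.  The tail is an exact log-space summation:
binomial coefficients via exact integer `math.comb`, logged, plus
`i·log p + (n−i)·log1p(−p)`, combined by max-shifted `fsum` log-sum-exp;
against a 60-digit Decimal oracle the relative error stays below 1e-12 for
n ≤ 500 even in extreme tails (measured in log space, so double underflow
cannot mask error).  Fold enrichment is rate_in/rate_out (flagged
undefined when k_out = 0, zero when k_in = 0); fold and mean-size ratios
are reported at full precision plus a round-half-up integer display value.
A single test is performed; no multiple-testing correction applies.

## Synthetic data (simgenome)

The generator emulates the study conditions the pipeline targets: a
reference genome of one or more chromosomes; strain genomes derived by
reverse-complementing planted intervals and substituting bases at
`snp_rate` (substitutions only — the scanner consumes alignment
coordinates, and indel realism adds noise without exercising new logic);
and fragmented assemblies cut from the strain genome.

Contig lengths are lognormal with σ = 0.5 and μ = ln(N50) − σ², so the
length-weighted median — which is what N50 estimates — equals the target
N50 (default 172,026 bp, the mean N50 of the short-read assemblies being
emulated); realized N50 stays within ±25% of target for genomes at least
~20× the target.  The real scaffold-length profile is heavier-tailed
(mean scaffold ≈ 13.5 kbp against N50 ≈ 172 kbp would need σ ≈ 2.25);
N50 fidelity was prioritized over scaffold-count fidelity because the
scanner's behavior depends on contig sizes relative to inversion spans,
not on the count of sub-N50 fragments.  Each planted breakpoint becomes a
contig boundary with probability `breakpoint_fragmentation_prob`,
exercising both the spanning-contig and the boundary-contig detection
paths.  Contigs below `min_contig_length` (default 500 bp) are dropped
and the rest emitted in shuffled order on their original strand.

Planted inversions within one strain must not overlap; polymorphic
overlapping clusters are represented across strains, which is also how
they occur in the data being modeled.  Planted sizes are a free choice of
the experimenter; the configurations here use 5 kbp–1.9 Mbp.  A
log-uniform range of 1 kbp–4 Mbp is a reasonable default for ad-hoc
configurations — the real sub-100 kbp size distribution is not published,
so this is a modeling choice, not a measured parameter.

Two stock configurations: desk scale (one 2 Mbp chromosome, 0.8 Mbp
suppressed region, six inversions of 5–500 kbp with the two > 100 kbp ones
inside the region, four strains in two lineages with mixed evidence tags)
runs the full pipeline in ~10 s; study scale (38,417,195 bp over seven
chromosomes, 8,320,000 bp suppressed region) is provided for larger runs.
Every random draw forks from one seed by stable string labels
(per stage, strain and chromosome), so outputs are byte-identical across
runs and per-stage reproducible.

What the simulations do **not** model: indels and rearrangements other
than inversions, sequencing error and coverage dropouts, repeat families
(unique-k-mer density in random sequence is higher than in real genomes),
assembly chimerism, and strand-shuffled contigs (above).  Passing tests
therefore demonstrate the correctness of the detection logic and
statistics under clean-to-moderately-diverged conditions, not performance
on repeat-rich real assemblies — where the repeat screen and manual
inspection matter more.

## Problem sizes and numerical choices

The test suite and the acceptance script use: one desk-scale pipeline run
(2 Mbp × 4 strains); 50 random 100 kbp two-inversion genomes for the
scanner-vs-oracle sweep; 1,000 random (k, n ≤ 500, p) triples for binomial
exactness; 500 replicates of 51 uniformly placed events for null
calibration (51 mirrors the reconstructed study event count; at region
fraction 0.4 the exact test's analytical size at α = 0.05 is 0.042, inside
the expected conservative band); and 20 seeds of 600 kbp genomes at
snp_rate = 0.005 for robustness.  These sizes are chosen so each property
is measured with comfortable margins while a full run stays interactive.

Study-scale enrichment inputs are the published region lengths (8,320,000
and 30,097,195 bp) and event counts reconstructed from the published
per-bp rates (9 in / 42 out over all inversions; 6 in / 1 out above
100 kbp).  From these the package computes rates 1.082 × 10⁻⁶ and
1.395 × 10⁻⁶ per bp, a 21.70-fold large-inversion enrichment (display 22),
p = 5.88 × 10⁻⁴ and a mean-size ratio of 45.45 (display 45) from the
printed means 1.5 vs 0.033 Mbp.  The published p of 0.00061 is ~4% above
the value recomputable from the published lengths and counts; the exact
supplementary counts or a slightly different region length would account
for the difference, so the recomputed value is reported as-is rather than
adjusted.

## Known limitations

* No split-read or sequence-level breakpoint refinement; resolution is set
  by anchor boundaries and the adjacency tolerance.
* Translocations, duplications and indels are out of scope; a transposed
  inverted copy would need the repeat screen to reject it.
* The aligner is a deterministic stand-in adequate for clean assemblies;
  it does not estimate identity in unanchored gaps and has no affine
  scoring.
* Fixation classification presumes complete strain sampling per lineage in
  the metadata; partial sampling biases it toward "fixed".
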