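# invscan

Chromosomal inversions — segments whose orientation is reversed relative to
a reference — are hard to see in short-read data: a fragmented de novo
assembly rarely contains a contig spanning a whole inverted block.  What it
does contain is the *breakpoint signature*: around an inversion of
reference interval [b₁+1, b₂], contigs align next to each other on the
reference in opposite directions, with a forward segment ending at b₁
adjacent to a reverse segment, and a reverse segment ending at b₂ adjacent
to a forward segment.  `invscan` detects inversions from exactly this
signature in whole-genome alignment coordinate tables, consolidates calls
across many strains into unique events, and tests whether large inversions
concentrate in a designated genomic region — the setting it is built for is
a fungal mating-type chromosome carrying a multi-megabase region of
suppressed recombination, compared across dozens of strain assemblies.

It is aimed at comparative genomicists who have (or simulate) per-strain
assemblies plus a reference, and want a tested, seedable path from FASTA to
an enrichment p-value.

## Method

1. **Alignment** (`anchor_align`): unique-k-mer anchors (canonical k=21)
   merged into maximal exact matches and greedily chained into collinear
   same-orientation segments (defaults `min_cluster=200`, `max_gap=2000`).
   Output is a 9-column coordinate table; a descending query range encodes
   reverse orientation.
2. **Scanning** (`inv_scan`): every reference-adjacent pair of segments
   with opposite orientations (within an adjacency tolerance, default
   5 kbp) becomes a breakpoint signal, `F|R` or `R|F`.  An `F|R` at b₁
   pairs with the farthest `R|F` at b₂ whose interval (b₁, b₂] is covered
   by reverse segments; the pair is one inversion call of size b₂ − b₁.
   Signals whose flanking segment has a secondary alignment covering ≥ 80%
   of the same contig interval are discarded as repeat artifacts; calls
   need both breakpoints.
3. **Consolidation** (`consolidate`): overlapping calls across strains form
   connected components that count as single events.  Filters: events
   < 1 kbp dropped; events > 100 kbp need two evidence types (e.g.
   Illumina + PacBio); events ≤ 100 kbp need two carrier strains.  Events
   are classified as fixed within a mating type per lineage.
4. **Enrichment** (`enrich`): each event is assigned to the region or the
   rest of the genome by its midpoint; with k_in of n events inside a
   region of length L_in out of a genome of length L_in + L_out, the
   one-sided exact binomial tail P(X ≥ k_in), X ~ Bin(n, L_in/(L_in+L_out)),
   is computed by exact log-space summation.  Per-bp rates k/L, the fold
   ratio and the mean-size ratio are reported alongside.

A synthetic-data module (`simgenome`) generates reference genomes, strain
genomes with planted (reverse-complemented) inversions and SNP divergence,
and lognormal-fragmented assemblies with a target N50, together with
ground-truth records — so the whole pipeline is verifiable without any
external download.

## Worked example

```python
from invscan.pipeline import run_all
from invscan.simgenome import default_desk_config

cfg = default_desk_config(seed=7, snp_rate=0.0)
cfg.breakpoint_fragmentation_prob = 1.0
result = run_all(cfg, "scratch/example_run")
print(result.recall, result.precision, result.enrichment["large"].k_in)
```

prints `1.0 1.0 2`: all six planted inversions (5 kbp – 500 kbp) on the
2 Mbp desk-scale chromosome are recovered as exactly six events with no
false positives, and both of the > 100 kbp events fall inside the 0.8 Mbp
suppressed region where they were planted.  The same run from the shell:

```bash
invscan run --config desk.yaml --out run1
# seed 7: 6 events, recall 1.000, precision 1.000; outputs in run1
```

`examples/` holds one short narrative script per capability (simulation,
align+scan, consolidation, enrichment, full pipeline); each prints the
numbers it computes and a line on what they mean.  At study scale
(`examples/04_enrichment_test.py`), 6 of the 7 large inversions inside an
8.32 Mbp suppressed region of a 38.4 Mbp genome give a 21.7-fold per-bp
enrichment with p = 5.9 × 10⁻⁴, while all inversions together are spread
evenly (1.08 × 10⁻⁶ vs 1.40 × 10⁻⁶ per bp).

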