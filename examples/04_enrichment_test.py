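"""Region-enrichment analysis at study scale.

Uses the published genome geometry (8,320,000 bp suppressed-recombination
region, 38,417,195 bp genome) and the event counts reconstructed from the
published per-bp rates (9 inversions inside / 42 outside; 6 of the >100 kbp
inversions inside / 1 outside) to recompute rates, fold enrichment, mean
size ratio and the one-sided exact binomial p-value.
"""

from invscan.consolidate import InversionEvent
from invscan.enrich import LARGE_SIZE_MIN, RegionPartition, compute_enrichment

partition = RegionPartition(intervals=(("chr1", 1_000_001, 9_320_000),),
                            genome_length=38_417_195)


def event(start, size):
    return InversionEvent(ref_id="chr1", start=start, end=start + size - 1,
                          members=[], strains=frozenset(),
                          evidence_types=frozenset())


events = [event(1_050_000 + i * 1_350_000, 200_000) for i in range(6)]   # large, in
events += [event(1_500_000 + i * 2_500_000, 20_000) for i in range(3)]   # small, in
events += [event(12_000_001, 150_000)]                                   # large, out
events += [event(13_000_001 + i * 400_000, 10_000) for i in range(41)]   # small, out

r_all = compute_enrichment(events, partition)
r_large = compute_enrichment(events, partition, min_size=LARGE_SIZE_MIN)

print(f"all inversions:   {r_all.k_in} in / {r_all.k_out} out;  "
      f"rates {r_all.rate_in:.3g} vs {r_all.rate_out:.3g} per bp")
print(f"> 100 kbp only:   {r_large.k_in} in / {r_large.k_out} out;  "
      f"fold {r_large.fold:.2f} (~{r_large.fold_display}-fold);  "
      f"p = {r_large.p_value:.3g} (one-sided binomial)")
print("Per base pair, all inversions are spread evenly (~1.1e-6 vs ~1.4e-6),"
      "\nbut the large ones concentrate ~22-fold in the suppressed region "
      "(p ~ 6e-4):\nlarge inversions accumulate where recombination cannot "
      "purge them.")
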