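"""Align one strain's fragmented assembly to the reference and scan the
coordinate table for inversion breakpoint signals.

Prints each aligned segment (orientation switches mark breakpoints) and the
paired inversion calls the scanner derives from them.
"""

from invscan.anchor_align import align_assembly
from invscan.inv_scan import scan_strain
from invscan.simgenome import (default_desk_config, fragment_assembly,
                               generate_reference, plant_inversions)

cfg = default_desk_config(seed=42, snp_rate=0.002)
ref = generate_reference(cfg)
strain = cfg.strains[0]
genome = plant_inversions(ref, cfg, strain.strain_id)
assembly = fragment_assembly(genome, cfg, strain.strain_id)

rows = align_assembly(ref, assembly)
print(f"{strain.strain_id}: {len(assembly)} contigs -> {len(rows)} aligned segments")
for r in rows:
    orient = "R" if r.is_reverse else "F"
    print(f"  {r.ref_id}:{r.ref_start:>9}-{r.ref_end:<9} {orient} {r.qry_id}")

calls = scan_strain(rows, strain.strain_id, evidence_type=strain.evidence_type)
paired = [c for c in calls if c.status == "paired"]
print(f"\n{len(paired)} paired inversion calls (both breakpoints found):")
for c in paired:
    print(f"  {c.ref_id}:{c.start}-{c.end}  size {c.size:,} bp")
print("Truth for this strain:",
      [(i.start, i.end) for i in cfg.inversions_for(strain.strain_id)])
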