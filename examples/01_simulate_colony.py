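"""Simulate a closed breeding colony segregating a recessive trait.

Builds the default study conditions (~123 cats, a fully penetrant
recessive causal variant on a 1.3 Mb ancestral haplotype near the end of
chromosome F1), drops founder haplotypes through the pedigree with
Haldane recombination, and prints the colony composition.
"""

import colonymap as cm

cfg = cm.default_colony(seed=7)
ped = cm.simulate_pedigree(cfg)
hapset, geno = cm.gene_drop(ped, cfg)
ped = cm.assign_phenotypes(ped, hapset)

print(f"colony size:        {len(ped)} ({len(ped.founders())} founders)")
print(f"affected:           {len(ped.affected_ids())}")
print(f"obligate carriers:  {len(ped.obligate_carrier_ids())}")
print(f"genome-wide sites:  {geno.n_sites}")
lo, hi = cfg.segment_bounds
print(f"IBD disease segment: {cfg.causal_chromosome}:{lo}-{hi} "
      f"({(hi - lo + 1) / 1e6:.1f} Mb), causal at {cfg.causal_position}")

# All affected carry two copies of the ancestral disease haplotype at the
# causal site, which is what the downstream mapping stages exploit.
ibd_lo, ibd_hi = cm.ibd_interval_from_origins(hapset, ped.affected_ids())
print(f"realized shared IBD core among affected: {ibd_lo}-{ibd_hi} "
      f"({(ibd_hi - ibd_lo) / 1e6:.2f} Mb)")
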