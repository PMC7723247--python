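"""Zygosity mapping: filter recessive-compatible variants and test clustering.

Labels 8 affected individuals and 6 obligate carriers (the WGS subset of
the study design), keeps variants homozygous-alt in all called affected
and heterozygous in all called carriers (calls from at least 11 of the 14
labeled animals), and asks whether the survivors cluster in the genome
with a chi-square test over 5 Mb windows.
"""

import colonymap as cm
from colonymap.zygosity import ZygosityFilterConfig

cfg = cm.default_colony(seed=7)
ped = cm.simulate_pedigree(cfg)
hapset, geno = cm.gene_drop(ped, cfg)
ped = cm.assign_phenotypes(ped, hapset)
dosages = hapset.causal_dosages()

affected = sorted(ped.affected_ids())[:8]
carriers = sorted(i for i in ped.obligate_carrier_ids() if dosages[i] == 1)[:6]
zcfg = ZygosityFilterConfig(affected, carriers, min_called=11)
res = cm.zygosity_filter(geno, zcfg)
print(f"{len(res.passing_index)} of {geno.n_sites} variants pass the zygosity filter")

genome = {c: length for c, length, _ in cfg.genome}
cluster = cm.cluster_enrichment(
    res.passing_sites, genome, window_size=5_000_000, tested_sites=geno.sites
)
peak = cluster.peak_window
print(f"chi-square X2 = {cluster.statistic:.1f}, df = {cluster.df}, "
      f"p = {cluster.p_value:.3g}")
print(f"peak window: {peak['chrom']}:{peak['start']}-{peak['end']} "
      f"({int(peak['observed'])} variants, residual {peak['residual']:.1f})")
print("A tiny p-value with the peak window on the causal chromosome means the "
      "recessive-compatible variants are not randomly scattered: they pile up "
      "around the disease locus.")
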