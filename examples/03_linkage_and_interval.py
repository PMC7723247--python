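"""Parametric linkage on the marker panel and critical-interval delineation.

Computes single-marker LOD scores under the fully penetrant rare
recessive model (theta = 0 vs 0.5, disease allele frequency 0.001) by
summing exact nuclear-family likelihoods, then delineates the critical
interval as the run of markers over which every affected individual is
homozygous for the shared disease haplotype.
"""

import numpy as np

import colonymap as cm

res = cm.run_colony_study(cm.default_colony(seed=7))

table = cm.lod_scan(res.pedigree, res.panel, decompose=True)
finite = table[np.isfinite(table["lod"])]
best = finite.loc[finite["lod"].idxmax()]
off = finite[finite["chrom"] != res.causal[0]]
print(f"panel: {res.panel.n_sites} markers")
print(f"peak LOD: {best['lod']:.1f} at {best['chrom']}:{best['pos']}")
print(f"max off-chromosome LOD: {off['lod'].max():.2f}")

iv = res.interval
print(f"critical interval (inner): {iv.chrom}:{iv.inner_start}-{iv.inner_end} "
      f"({iv.inner_span / 1e6:.2f} Mb)")
print(f"critical interval (outer): {iv.chrom}:{iv.outer_start}-{iv.outer_end} "
      f"({iv.outer_span / 1e6:.2f} Mb)")
print(f"causal variant at {res.causal[0]}:{res.causal[1]} -> "
      f"inside interval: {res.interval_contains_causal}")
print("A LOD above 3 is the classical genome-wide significance line for "
      "linkage; the interval bounds are set by the nearest recombinant "
      "markers flanking the shared homozygous run.")
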