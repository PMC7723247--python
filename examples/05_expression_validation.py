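"""Expression-level validation of a nonsense-mediated-decay candidate.

Simulates cortex RNA-seq for 4 homozygous mutant, 3 heterozygous and 3
homozygous reference animals with mutant-allele retention lambda = 0.41,
then measures: the total transcript reduction in homozygotes, the
mutant-allele read bias in heterozygotes, the dual-contrast FDR
intersection of differentially expressed genes, and genotype effects on
cell-type marker panels.
"""

import colonymap as cm
from colonymap.expression import nb_lrt_de

cfg = cm.ExpressionSimConfig(seed=7, n_de_genes=10, de_log2fc=2.0)
dosages = {f"A{i}": 2 for i in range(4)}
dosages |= {f"H{i}": 1 for i in range(3)}
dosages |= {f"R{i}": 0 for i in range(3)}
bundle = cm.simulate_expression(None, dosages, cfg)
cpm = cm.cpm_normalize(bundle.counts, bundle.library_sizes)

red = cm.expression_reduction_test(cpm, bundle.groups, bundle.target_gene)
print(f"target-gene reduction in homozygotes: {red.percent_reduction:.1f}% "
      f"(simulated truth 59%), one-way ANOVA p = {red.anova_p:.2g}")

bias = cm.allele_bias_test(
    bundle.allele_counts, bundle.target_gene, list(bundle.control_genes)
)
print(f"het mutant-read fraction: {bias.gene_means[bundle.target_gene]:.3f} "
      f"(theory pi = {cfg.het_mutant_fraction:.3f}), ANOVA p = {bias.anova_p:.2g}")

de_a = nb_lrt_de(bundle.counts, bundle.groups, "hom_mutant", ["het", "hom_ref"])
de_b = nb_lrt_de(bundle.counts, bundle.groups, "hom_mutant", "hom_ref")
inter = cm.de_intersection(de_a, de_b)
print(f"genes significant (q<0.05, concordant) in BOTH contrasts: "
      f"{len(inter['concordant'])}")

markers = cm.select_celltype_markers(bundle.cell_type_reference)
shifts = cm.celltype_shift_test(cpm, markers, bundle.groups)
print("\ncell-type genotype effects (permutation p of the two-way ANOVA F):")
print(shifts.to_string(index=False))
print("\nOPC/astrocyte/endothelial panels shift up and oligodendrocytes down "
      "in mutants by construction; neuron and microglia panels are null.")
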