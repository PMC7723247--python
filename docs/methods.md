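# Methods

This note documents the models, statistics and numerical choices behind
colonymap, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## The mapping model

The trait model throughout is a fully penetrant autosomal recessive:
penetrance (0, 0, 1) over copies of the disease allele, no phenocopies,
disease allele frequency q = 0.001 ("rare recessive"). All loci are
autosomal; sex chromosomes are not modeled.

### Zygosity filter

A biallelic site is compatible with the model when every *called* affected
individual has alternate-allele dosage 2 and every called obligate carrier
(an unaffected parent of an affected animal, necessarily heterozygous
under full penetrance) has dosage 1. A single called violation fails the
site outright; missing calls are tolerated down to `min_called` labeled
calls (default 11, matching the canonical 8-affected + 6-carrier
labeling with up to three missing calls). Carriers are required to be exactly heterozygous: an
obligate carrier homozygous for the alternate allele is impossible under
full penetrance.

### Cluster enrichment

Compatible sites are counted in fixed genomic windows (default 5 Mb;
chromosomes with no tested variants are excluded; a trailing partial
window shorter than half the window size is merged into its neighbour to
avoid small-expectation cells). Under the default `uniform` null each of
the W windows expects K/W of the K passing variants; X² = Σ (O−E)²/E is
referred to the chi-square distribution with W−1 degrees of freedom, and
per-window standardized residuals locate the peak. Because callable
density is not uniform in real data, a `tested_density` null (expectations
proportional to tested variants per window) is available and is what the
pipeline uses when the full tested site list is at hand. The calibration
simulations use 400 variants over 20 windows, i.e. expected counts of 20
per window, keeping the chi-square reference inside its large-sample
(Cochran) regime; with expected counts near 10 the upper tail is visibly
anticonservative.

### Exact two-point LOD

The single-marker likelihood at recombination fraction θ sums over founder
phased two-locus diplotypes (Hardy–Weinberg and linkage-equilibrium
priors; marker allele frequencies equal by default, optionally estimated
from founders) and per-meiosis transmission outcomes (which parental
haplotype supplied the disease locus, and whether a recombination
separated it from the marker). LOD = log₁₀ L(0) − log₁₀ L(0.5), evaluated
only at θ ∈ {0, ½}.

The sum is computed exactly by sum-product variable elimination over
per-individual phased two-locus states ((2k)² states for k marker
alleles): founder factors carry priors and evidence, child factors carry
the transmission tensor, and greedy minimum-cluster elimination handles
looped pedigrees without loop-breaking approximations. Every intermediate
is rescaled by its maximum with the scale accumulated in log10, so deep
pedigrees cannot underflow. An explicit state budget (default 2×10⁷
entries) turns an oversized elimination cluster into an error that
recommends nuclear-family decomposition; `sum_nuclear_family_lods` and
`lod_scan(..., decompose=True)` implement that standard fallback, which is
what the colony-scale scans use. Genotype configurations impossible at
θ = 0 but possible at θ = ½ yield LOD = −∞ with an explicit flag; markers
impossible at any θ raise a Mendelian-inconsistency error.

A literal brute-force oracle (`lod_enumeration_oracle`) enumerates founder
states and all 4^meioses transmission outcomes, refuses pedigrees beyond a
configurable meiosis limit (default 10), and is required by the test suite
to agree with the elimination engine within 1e-9 log10 units on randomized
pedigrees; the phase-unknown carrier×carrier family with n affected
children reproduces the closed form (n−1)·log₁₀ 4. LOD at θ = 0 is
insensitive to q for within-pedigree data; a test sweeps
q ∈ {1e-4, 1e-3, 1e-2}. Unknown phenotypes receive penetrance 1 for every
genotype (uninformative), the standard parametric-linkage convention.

### Diplotype reconstruction

Phasing is rule-based and never guesses: a marker is phased only when
Mendelian transmission forces it (homozygous child; heterozygous child
with a homozygous parent; forced complement within a trio). Untyped
parents are imputed from a genotyped mate and progeny — the transmitted
haplotype equals the child haplotype not attributable to the mate — using
a single child per parent, because merging transmissions across children
would chimerize distinct recombinant gametes. The imputed haplotype is
therefore a real *transmitted* gamete, possibly itself a recombinant
mosaic of the parent's two haplotypes; the second haplotype is the
genotype complement where known and uncertain otherwise. Mendelian
conflicts are flagged, reported, and the marker is excluded for that
family. The truth-comparison tests assert exact agreement with the
simulator's haplotypes at every trio-forced position.

### Critical interval

The interval is the contiguous run of markers at which every called
affected individual is homozygous for one shared allele (the consensus
disease-haplotype allele). Both inner bounds (first/last run markers) and
outer bounds (nearest flanking violating markers, or panel ends) are
reported; the physical truth lies between them, so both are emitted rather
than choosing one convention. Without further information the longest run
is returned; the pipeline instead anchors the search at the zygosity-peak
signal (`anchor=`), which is how fine-mapping actually proceeds and which
keeps the interval correct even when many affected animals and accumulated
recombination shrink the shared core below chance shared-homozygosity runs
elsewhere. With origin-labeled simulated haplotypes,
`ibd_interval_from_origins` returns the true identical-by-descent core for
comparison.

### Prioritization

Variants inside the interval are dropped when their population allele
frequency is ≥ 5% (absent-from-database is treated as frequency 0 and
printed "Absent"). Ranking is a deterministic total order: consequence
tier (frameshift and other loss-of-function > missense and in-frame
indel > synonymous and noncoding), then usable CADD descending (missing
below present within a tier), then an expressed-in-tissue flag
(CPM ≥ 1 by default — used as a flag and tie-break, not a hard filter, to
avoid discarding low-expression true positives), then (chromosome,
position, alt) so permuting input rows can never change the order. A CADD
score is unusable when the variant failed liftover or when the
human-consequence the score derives from is non-synonymous while the
species consequence is synonymous (the score-inflation case); such scores
are flagged and never outrank unflagged coding variants. GERP is carried
but not used in ranking. Coding effects are annotated against a minimal
transcript model (ordered CDS exons, strand, spliced coding sequence) with
a built-in codon table; an indel whose length change is not a multiple of
three inside the CDS is a frameshift; the `inframe` category covers
length-preserving indels, which the consequence tiers place with missense.
The codon containing coding nucleotide c is ⌊(c−1)/3⌋ + 1.

## Expression validation

The nonsense-mediated-decay model is parameterized by the mutant-allele
retention λ ∈ [0, 1] (mutant transcript output relative to wild type):
homozygote mean expression is λ × baseline (reduction 1 − λ; 59% at the
default λ = 0.41), heterozygote mean is (1 + λ)/2 × baseline, and the
heterozygote mutant-read fraction is π = λ/(1 + λ) ≈ 0.2908.

- **Reduction test**: percent reduction on the CPM scale,
  (1 − mean(hom mutant)/mean(hom ref)) × 100, with a one-way ANOVA across
  the three genotype groups and Tukey post-hoc contrasts.
- **Allele bias**: per-cat mutant-read fractions alt/(ref+alt) per gene;
  one-way ANOVA of the target against nearby control genes with Tukey
  post-hoc. Because per-measurement depths span 24–3000 reads and binomial
  variance scales as 1/depth, the ANOVA weights each fraction by its depth
  by default, which keeps the F reference exactly calibrated; the
  unweighted per-cat comparison is available via `weighted=False`.
- **Differential expression**: the per-gene test is a stand-in by design —
  either a Welch test on log2(CPM+1) or a negative-binomial likelihood
  ratio test on raw counts with a shared dispersion estimated by
  Cox–Reid-adjusted profile likelihood (common-dispersion estimation in
  the edgeR style) and log library-size offsets. The NB-LRT is the one
  with usable power at the pipeline's group sizes (4/3/3) and is what the
  recovery and FDR tests use. The pipeline-defined content is the
  contrast design (homozygous mutant vs homozygous reference, vs all
  unaffected, heterozygous vs reference) and the strict dual-significance
  intersection: a gene counts only when q < 0.05 in both designated
  contrasts with concordant effect signs; discordant-sign genes are
  reported separately. FDR control is Benjamini–Hochberg step-up.
- **Cell-type composition**: a gene marks a cell type when its mean
  reference abundance is at least 2-fold (boundary inclusive) above every
  other type and a Welch test against the runner-up type has raw p < 0.2
  (strict); types with fewer than two replicates are excluded. The
  genotype effect on a marker panel is the two-way (genotype + gene)
  ANOVA F for genotype on log2(CPM+1), with its p-value taken from the
  exhaustive permutation distribution over the distinct sample labelings
  (4200 for groups of 4/3/3): with every gene measured in every sample the
  gene factor is orthogonal to any sample partition, so the F statistic is
  monotone in the between-group sum of squares of per-sample means, and
  samples are exchangeable under the null — the permutation reference is
  exactly calibrated where the parametric F drifts either way under
  per-gene variance heterogeneity. The parametric p remains available.
- **Brain weight**: per-animal brain (g) over body (kg); percent decrease
  of the affected group mean against all other animals pooled, rounded to
  the nearest integer percent.
- Sample exclusions (e.g. kittens or PCA outliers in a real study) are an
  explicit sample list upstream of every test, not an automated gate.

## The synthetic colony generator

The generator's defaults are the study conditions, chosen once:

- **Pedigree**: 12 founders, up to 5 discrete generations; each female of
  the previous generation is paired with a random male (full-sibling
  avoidance optional) and litters are Poisson with mean 4 (cat-like litter
  size); growth stops mid-generation at 123 individuals.
- **Genome**: 18 autosomes with cat-like lengths (~2.3 Gb total) at
  1 cM/Mb. Background variant density 2 per Mb (~4700 biallelic sites —
  a desk-scale thinning of a real variant set that keeps every stage's
  computational structure); the 1.3 Mb disease segment on chromosome F1 is
  enriched to 20 per Mb so the critical interval holds a realistic
  candidate set.
- **Disease haplotype**: 45% of founder haplotypes carry one identical
  ancestral segment (alternate alleles across the 1.3 Mb window, a
  dedicated founder-origin label, and the causal variant at F1:66,768,323
  carried by no other haplotype). A closed colony descends from few
  related animals, so modeling the founders as already sharing the
  ancestral haplotype is what makes ~20% of the colony homozygous
  (≈25 affected of 123) without modeling selective breeding. Segment
  sites carry the alternate allele at frequency 0.10 on non-disease
  haplotypes; other sites draw founder frequencies uniform on (0.1, 0.9).
- **Gene drop**: per meiosis and chromosome the crossover count is Poisson
  with mean equal to the map length in Morgans (Haldane, no interference)
  with breakpoints uniform under a linear cM–bp map; child haplotypes are
  recombinant mosaics of exactly one parent's two haplotypes, so Mendelian
  consistency holds by construction and is asserted exhaustively.
  Phenotypes are deterministic from the causal genotype. Genotype dropout
  is available (default 0) to exercise the zygosity filter's missing-call
  tolerance.
- **Marker panel**: 26 markers evenly spaced over the 70 Mb panel interval
  containing the candidate region, 4 over the rest of the causal
  chromosome, 20 spread across other chromosomes; only polymorphic sites
  are eligible and each stratum errors explicitly when it cannot be
  filled.
- **Expression**: negative-binomial counts (shared dispersion 0.1;
  per-gene dispersion optional) for 2000 genes over 4/3/3 samples, the
  NMD scaling above for the target gene (baseline mean 3000 counts, in the
  highly-expressed range a brain-enriched transcript occupies),
  allele-specific depths log-uniform on 24–3000 reads, six cell types
  with 25 marker genes each (reference 5-fold enriched, 3 replicates) and
  genotype shift multipliers (OPC 1.6, oligodendrocyte 0.6, astrocyte 1.4,
  endothelial 1.3, neuron and microglia 1.0) emulating the composition
  shifts of the affected cortex. Optional planted DE genes (default
  4-fold in homozygous mutants) support the intersection-recovery and FDR
  simulations.

What the generator does *not* emulate — and hence what passing tests do
not demonstrate about real data: sequencing and alignment error,
batch/library effects and GC or length biases in counts, linkage
disequilibrium structure beyond the pedigree itself, selection or new
mutation during the pedigree, overlapping generations and non-random mate
choice, and per-gene dispersion trends. Determinism is a contract:
identical (configuration, seed) reproduces pedigree, haplotypes,
genotypes and counts exactly.

## Problem sizes used by the test suites

Monte-Carlo checks run at sizes chosen to make each property measurable at
desk scale: 100 seeded default colonies for end-to-end recovery; 100
random small pedigrees for oracle equivalence (25 in the unit suite);
2000 replicates for scalar-test calibration and 500 for the permutation
two-way test; 50 seeds for NMD parameter recovery; 20 planted-truth
bundles for empirical FDR. Calibration assertions use the two-sided 95%
binomial interval around the nominal level.

## Known limitations

- The exact-likelihood engine is built for desk-scale pedigrees; colony
  pedigrees beyond the state budget must be decomposed into nuclear
  families (exposed as a first-class option), which discards some
  cross-family information and typically understates the full-pedigree
  LOD.
- Diplotype imputation reports transmitted gametes; it cannot separate a
  recombinant transmitted haplotype into the untyped parent's two true
  haplotypes, and it does not attempt population-based phasing.
- The per-gene DE tests are deliberate stand-ins; shrinkage estimators of
  per-gene dispersion and fold change are out of scope.
- The cluster test treats windows as independent; the uniform null
  ignores callable-density variation unless the `tested_density` null is
  selected.
- CADD/GERP-style scores are consumed as annotations, never computed.
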