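"""RNA-seq simulator for nonsense-mediated-decay validation.

Counts are negative-binomial per gene.  The NMD model is parameterized by
the mutant-allele retention fraction ``lambda`` (transcript output of the
mutant allele relative to wild type):

* homozygous mutant total expression = ``lambda`` x baseline, i.e. a
  reduction of ``1 - lambda`` (default 0.59 with ``lambda = 0.41``);
* heterozygote total expression = ``(1 + lambda) / 2`` x baseline;
* heterozygote mutant-read fraction ``pi = lambda / (1 + lambda)``
  (~0.2908 at the default).

Cell-type marker genes receive genotype-specific fold shifts emulating
altered cellular composition in affected cortex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .simulate import ConfigError

GROUPS = ("hom_mutant", "het", "hom_ref")

DEFAULT_CELL_TYPES: dict[str, tuple[int, float]] = {
    # cell type -> (n marker genes, hom_mutant fold shift)
    "OPC": (25, 1.6),
    "oligodendrocyte": (25, 0.6),
    "astrocyte": (25, 1.4),
    "endothelial": (25, 1.3),
    "neuron": (25, 1.0),
    "microglia": (25, 1.0),
}


@dataclass
class ExpressionSimConfig:
    n_genes: int = 2000
    baseline_log_mean: float = 5.0  # natural-log mean of per-gene NB means
    baseline_log_sd: float = 1.0
    dispersion: float = 0.1
    per_gene_dispersion: bool = False
    nmd_retention: float = 0.41  # lambda
    target_gene: str = "PEA15"
    target_baseline: float = 3000.0
    control_genes: tuple[str, ...] = ("CTRL_1", "CTRL_2", "CTRL_3")
    reads_range: tuple[int, int] = (24, 3000)  # allele-specific depth per gene per cat
    replicates: dict[str, int] = field(
        default_factory=lambda: {"hom_mutant": 4, "het": 3, "hom_ref": 3}
    )
    cell_types: dict[str, tuple[int, float]] = field(
        default_factory=lambda: dict(DEFAULT_CELL_TYPES)
    )
    reference_replicates: int = 3
    reference_fold: float = 5.0
    n_de_genes: int = 0
    de_log2fc: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.nmd_retention <= 1.0):
            raise ConfigError("nmd_retention (lambda) must be in [0, 1]")
        if self.dispersion < 0 or self.n_genes < 1:
            raise ConfigError("dispersion must be >= 0 and n_genes >= 1")
        if any(n < 0 for n in self.replicates.values()):
            raise ConfigError("replicate counts must be >= 0")

    @property
    def homozygote_reduction(self) -> float:
        """Implied total-expression reduction in homozygotes, r = 1 - lambda."""
        return 1.0 - self.nmd_retention

    @property
    def het_mutant_fraction(self) -> float:
        """Implied heterozygote mutant-read fraction, pi = lambda / (1 + lambda)."""
        lam = self.nmd_retention
        return lam / (1.0 + lam)


@dataclass
class ExpressionBundle:
    counts: pd.DataFrame  # genes x samples, integer counts
    groups: pd.Series  # sample -> group label
    library_sizes: pd.Series
    allele_counts: pd.DataFrame  # sample, gene, ref_reads, alt_reads
    cell_type_reference: pd.DataFrame  # gene, cell_type, replicate, abundance
    target_gene: str
    control_genes: tuple[str, ...]
    marker_genes: dict[str, list[str]]


def _nb_counts(
    mean: np.ndarray, dispersion: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + alpha mu^2; alpha=0 is Poisson."""
    mean = np.clip(mean, 0.0, None)
    out = np.zeros_like(mean)
    pois = dispersion == 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        a = dispersion[~pois]
        lam = rng.gamma(shape=1.0 / a, scale=mean[~pois] * a)
        out[~pois] = rng.poisson(lam)
    return out


def _gene_names(cfg: ExpressionSimConfig) -> tuple[list[str], dict[str, list[str]], list[str]]:
    markers = {
        t: [f"{t.upper()[:4]}_{i:03d}" for i in range(n)]
        for t, (n, _shift) in cfg.cell_types.items()
    }
    de = [f"DE_{i:03d}" for i in range(cfg.n_de_genes)]
    special = (
        [cfg.target_gene]
        + list(cfg.control_genes)
        + [g for gs in markers.values() for g in gs]
        + de
    )
    n_bg = max(0, cfg.n_genes - len(special))
    genes = special + [f"G{i:05d}" for i in range(n_bg)]
    return genes, markers, de


def simulate_expression(
    pedigree: Pedigree | None,
    causal_dosages: dict[str, int],
    config: ExpressionSimConfig,
    seed: int | None = None,
) -> ExpressionBundle:
    """Simulate a count matrix, allele-specific reads and a cell reference.

    Samples are drawn from ``causal_dosages`` (dosage 2 = hom_mutant,
    1 = het, 0 = hom_ref) to fill the per-group replicate counts; ids are
    taken in sorted order for reproducibility.  ``pedigree`` is accepted
    for interface symmetry and optional id validation.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if pedigree is not None:
        unknown = [i for i in causal_dosages if i not in pedigree]
        if unknown:
            raise ConfigError(f"dosage ids not in pedigree: {unknown[:5]}")
    by_group: dict[str, list[str]] = {g: [] for g in GROUPS}
    code = {2: "hom_mutant", 1: "het", 0: "hom_ref"}
    for iid in sorted(causal_dosages):
        d = causal_dosages[iid]
        if d in code:
            by_group[code[d]].append(iid)
    samples: list[str] = []
    labels: list[str] = []
    for g in GROUPS:
        want = config.replicates.get(g, 0)
        have = by_group[g]
        if len(have) < want:
            raise ConfigError(
                f"need {want} samples in group {g}, only {len(have)} available"
            )
        samples.extend(have[:want])
        labels.extend([g] * want)
    groups = pd.Series(labels, index=samples, name="group")

    genes, markers, de_genes = _gene_names(config)
    n_genes, n_samples = len(genes), len(samples)
    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n_genes)
    gi = {g: i for i, g in enumerate(genes)}
    base[gi[config.target_gene]] = config.target_baseline

    lam = config.nmd_retention
    dose_scale = {"hom_mutant": lam, "het": (1.0 + lam) / 2.0, "hom_ref": 1.0}
    mean = np.tile(base[:, None], (1, n_samples))
    for j, s in enumerate(samples):
        g = groups[s]
        mean[gi[config.target_gene], j] *= dose_scale[g]
        if g == "hom_mutant":
            for t, (_n, shift) in config.cell_types.items():
                for m in markers[t]:
                    mean[gi[m], j] *= shift
            for m in de_genes:
                mean[gi[m], j] *= 2.0 ** config.de_log2fc
    if config.per_gene_dispersion:
        disp = rng.uniform(0.5, 1.5, size=n_genes) * config.dispersion
    else:
        disp = np.full(n_genes, config.dispersion)
    counts = _nb_counts(mean, np.tile(disp[:, None], (1, n_samples)), rng)
    counts_df = pd.DataFrame(counts.astype(int), index=genes, columns=samples)
    lib = counts_df.sum(axis=0).astype(float)
    lib.name = "library_size"

    # allele-specific reads at heterozygous coding sites
    pi = config.het_mutant_fraction
    lo, hi = config.reads_range
    ac_rows = []
    for s in samples:
        if groups[s] != "het":
            continue
        for gene in [config.target_gene, *config.control_genes]:
            depth = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
            frac = pi if gene == config.target_gene else 0.5
            alt = int(rng.binomial(depth, frac))
            ac_rows.append((s, gene, depth - alt, alt))
    allele_counts = pd.DataFrame(
        ac_rows, columns=["sample", "gene", "ref_reads", "alt_reads"]
    )

    reference = simulate_celltype_reference(config, rng)
    return ExpressionBundle(
        counts_df,
        groups,
        lib,
        allele_counts,
        reference,
        config.target_gene,
        tuple(config.control_genes),
        markers,
    )


def simulate_celltype_reference(
    config: ExpressionSimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Cell-type reference abundances with replicated enriched markers.

    Each cell type's marker genes are ``reference_fold`` enriched over all
    other types; replicates carry modest lognormal noise.
    """
    rng = rng or np.random.default_rng(config.seed + 0xCE11)
    rows = []
    types = list(config.cell_types)
    _genes, markers, _de = _gene_names(config)
    for t in types:
        for gene in markers[t]:
            base = rng.lognormal(3.0, 0.3)
            for other in types:
                level = base * (config.reference_fold if other == t else 1.0)
                for r in range(config.reference_replicates):
                    rows.append(
                        (gene, other, r, level * rng.lognormal(0.0, 0.15))
                    )
    return pd.DataFrame(rows, columns=["gene", "cell_type", "replicate", "abundance"])
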