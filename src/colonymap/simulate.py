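"""Synthetic closed-colony generator: pedigree, gene drop, marker panel.

The generator emulates the mapping substrate of a closed breeding colony in
which a fully penetrant recessive trait segregates on a single ancestral
founder haplotype: a multi-generation pedigree of ~123 individuals, genome
wide biallelic variants dropped through the pedigree with Haldane (no
interference) recombination, a 1.3 Mb identical-by-descent disease segment
shared by all affected individuals, and an amplicon-style marker panel
(26 markers across the candidate interval, 4 more on the causal chromosome,
20 genome-wide).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .pedigree import Individual, Pedigree, Phenotype, Sex


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# Cat-like autosome lengths (bp); genetic map defaults to 1 cM per Mb.
DEFAULT_GENOME: tuple[tuple[str, int, float], ...] = (
    ("A1", 240_000_000, 240.0),
    ("A2", 171_000_000, 171.0),
    ("A3", 143_000_000, 143.0),
    ("B1", 208_000_000, 208.0),
    ("B2", 155_000_000, 155.0),
    ("B3", 149_000_000, 149.0),
    ("B4", 144_000_000, 144.0),
    ("C1", 222_000_000, 222.0),
    ("C2", 161_000_000, 161.0),
    ("D1", 117_000_000, 117.0),
    ("D2", 90_000_000, 90.0),
    ("D3", 96_000_000, 96.0),
    ("D4", 96_000_000, 96.0),
    ("E1", 63_000_000, 63.0),
    ("E2", 64_000_000, 64.0),
    ("E3", 44_000_000, 44.0),
    ("F1", 83_000_000, 83.0),
    ("F2", 85_000_000, 85.0),
)


@dataclass
class MarkerPanelSpec:
    interval_markers: int = 26
    chromosome_markers: int = 4
    genomewide_markers: int = 20


@dataclass
class ColonyConfig:
    """Study conditions for the synthetic colony.

    Defaults mirror the mapped colony: ~123 cats over a handful of
    generations, a recessive causal variant near the distal end of
    chromosome F1 on a 1.3 Mb ancestral haplotype segregating at high
    frequency (the colony descends from a small related founder group),
    and a 26/4/20 amplicon marker panel.
    """

    n_founders: int = 12
    n_generations: int = 5
    mating_scheme: str = "random_within_colony"  # or "sibling_avoidance"
    mean_offspring: float = 4.0
    target_colony_size: int = 123
    causal_chromosome: str = "F1"
    causal_position: int = 66_768_323
    ibd_segment_length: int = 1_300_000
    genome: tuple[tuple[str, int, float], ...] = DEFAULT_GENOME
    variant_density: float = 2.0  # background variants per Mb
    interval_variant_density: float = 20.0  # extra density inside the IBD segment
    marker_panel_spec: MarkerPanelSpec = field(default_factory=MarkerPanelSpec)
    panel_interval: tuple[int, int] = (13_000_001, 83_000_000)
    disease_hap_freq: float = 0.45  # among founder haplotypes
    segment_background_af: float = 0.10
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        chroms = {c: (length, cm) for c, length, cm in self.genome}
        if self.causal_chromosome not in chroms:
            raise ConfigError(
                f"causal chromosome {self.causal_chromosome!r} absent from genome"
            )
        length, _ = chroms[self.causal_chromosome]
        if not (1 <= self.causal_position <= length):
            raise ConfigError(
                f"causal position {self.causal_position} outside "
                f"{self.causal_chromosome} (1..{length})"
            )
        if any(length <= 0 or cm < 0 for _, length, cm in self.genome):
            raise ConfigError("chromosome lengths must be > 0 and maps >= 0 cM")
        if self.n_founders < 1 or self.n_generations < 0 or self.target_colony_size < 1:
            raise ConfigError("counts must be positive")
        if self.mating_scheme not in ("random_within_colony", "sibling_avoidance"):
            raise ConfigError(f"unknown mating scheme {self.mating_scheme!r}")
        if not (0.0 < self.disease_hap_freq < 1.0):
            raise ConfigError("disease_hap_freq must be in (0, 1)")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise ConfigError("dropout_prob must be in [0, 1)")
        spec = self.marker_panel_spec
        if min(spec.interval_markers, spec.chromosome_markers, spec.genomewide_markers) < 0:
            raise ConfigError("marker panel counts must be >= 0")

    @property
    def segment_bounds(self) -> tuple[int, int]:
        """1-based inclusive bounds of the IBD disease segment."""
        start = max(1, self.causal_position - self.ibd_segment_length // 2)
        return start, start + self.ibd_segment_length - 1


@dataclass
class HaplotypeSet:
    """True phased haplotypes with founder-origin labels per site.

    ``haps[i, k, s]`` is the allele (0/1) of haplotype ``k`` (0 paternal,
    1 maternal; arbitrary for founders) of individual ``i`` at site ``s``;
    ``origins`` carries the founder haplotype label each segment descends
    from.  All copies of the ancestral disease haplotype share the
    dedicated ``disease_origin`` label inside the IBD segment.
    """

    sites: pd.DataFrame
    ids: list[str]
    haps: np.ndarray  # (n_ind, 2, n_sites) int8
    origins: np.ndarray  # (n_ind, 2, n_sites) int16
    disease_origin: int
    causal_index: int
    segment_bounds: tuple[int, int]

    def index_of(self, iid: str) -> int:
        return self.ids.index(iid)

    def causal_dosages(self) -> dict[str, int]:
        return {
            iid: int(self.haps[i, :, self.causal_index].sum())
            for i, iid in enumerate(self.ids)
        }


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigree(config: ColonyConfig, seed: int | None = None) -> Pedigree:
    """Grow a discrete-generation colony pedigree up to the target size.

    Each generation, every female of the previous generation is paired with
    a random male of that generation (optionally avoiding full siblings)
    and produces a Poisson-distributed litter.  Growth stops mid-generation
    once the colony reaches ``target_colony_size``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    inds: list[Individual] = []
    for k in range(config.n_founders):
        sex = Sex.MALE if k % 2 == 0 else Sex.FEMALE
        inds.append(Individual(f"G0_{k:03d}", sex=sex))
    prev = list(inds)
    parents_of = {i.iid: (None, None) for i in inds}
    total = len(inds)
    for g in range(1, config.n_generations + 1):
        males = [i for i in prev if i.sex is Sex.MALE]
        females = [i for i in prev if i.sex is Sex.FEMALE]
        if not males or not females:
            if g == 1:
                raise ConfigError(
                    "mating impossible: founders lack both sexes"
                )
            break
        children: list[Individual] = []
        kid = 0
        any_mating = False
        for dam in females:
            if total >= config.target_colony_size:
                break
            candidates = males
            if config.mating_scheme == "sibling_avoidance":
                dp = parents_of[dam.iid]
                candidates = [
                    m
                    for m in males
                    if dp == (None, None)
                    or parents_of[m.iid] != dp
                ]
                if not candidates:
                    continue
            sire = candidates[rng.integers(len(candidates))]
            any_mating = True
            for _ in range(rng.poisson(config.mean_offspring)):
                if total >= config.target_colony_size:
                    break
                child = Individual(
                    f"G{g}_{kid:03d}",
                    sire=sire.iid,
                    dam=dam.iid,
                    sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
                )
                parents_of[child.iid] = (sire.iid, dam.iid)
                children.append(child)
                kid += 1
                total += 1
        if g == 1 and not any_mating and total < config.target_colony_size:
            raise ConfigError(
                f"mating impossible under scheme {config.mating_scheme!r} "
                f"with {config.n_founders} founder(s)"
            )
        inds.extend(children)
        prev = children
        if total >= config.target_colony_size or not children:
            break
    return Pedigree(inds)


# ---------------------------------------------------------------------------
# Site list and founder haplotypes
# ---------------------------------------------------------------------------

def _draw_sites(config: ColonyConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows: list[tuple[str, int, str, str]] = []
    seg_lo, seg_hi = config.segment_bounds
    for chrom, length, _cm in config.genome:
        n_bg = int(round(length / 1e6 * config.variant_density))
        pos = np.unique((rng.random(n_bg) * length).astype(np.int64) + 1)
        for p in pos:
            rows.append((chrom, int(p), "A", "G"))
        if chrom == config.causal_chromosome:
            n_seg = int(round(config.ibd_segment_length / 1e6 * config.interval_variant_density))
            seg_pos = np.unique(
                (rng.random(n_seg) * config.ibd_segment_length).astype(np.int64) + seg_lo
            )
            for p in seg_pos:
                rows.append((chrom, int(p), "C", "T"))
            rows.append((chrom, config.causal_position, "GT", "G"))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    sites = sites.drop_duplicates(subset=["chrom", "pos"], keep="last")
    return sites.sort_values(["chrom", "pos"]).reset_index(drop=True)


def _founder_haplotypes(
    config: ColonyConfig, sites: pd.DataFrame, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Alleles and origin labels for the 2*n_founders founder haplotypes."""
    n_hap = 2 * config.n_founders
    n_sites = len(sites)
    pos = sites["pos"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    seg_lo, seg_hi = config.segment_bounds
    on_causal = chrom == config.causal_chromosome
    in_segment = on_causal & (pos >= seg_lo) & (pos <= seg_hi)
    causal_idx = int(
        np.flatnonzero(on_causal & (pos == config.causal_position))[0]
    )

    freqs = rng.uniform(0.1, 0.9, size=n_sites)
    freqs[in_segment] = config.segment_background_af
    freqs[causal_idx] = 0.0
    alleles = (rng.random((n_hap, n_sites)) < freqs).astype(np.int8)

    n_disease = max(1, int(round(n_hap * config.disease_hap_freq)))
    disease_slots = rng.choice(n_hap, size=n_disease, replace=False)
    alleles[np.ix_(disease_slots, np.flatnonzero(in_segment))] = 1

    disease_origin = n_hap  # label reserved for the shared ancestral segment
    origins = np.tile(np.arange(n_hap, dtype=np.int16)[:, None], (1, n_sites))
    origins[np.ix_(disease_slots, np.flatnonzero(in_segment))] = disease_origin
    return alleles, origins, causal_idx, disease_origin


def _meiosis(
    hap_pair: np.ndarray,
    orig_pair: np.ndarray,
    chrom_slices: list[tuple[int, int, np.ndarray, int, float]],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete: per-chromosome Haldane (Poisson) crossovers, random start."""
    n_sites = hap_pair.shape[1]
    child = np.empty(n_sites, dtype=np.int8)
    corig = np.empty(n_sites, dtype=np.int16)
    for lo, hi, pos, length, morgans in chrom_slices:
        n_break = rng.poisson(morgans)
        start = int(rng.integers(2))
        if n_break == 0:
            src = np.full(pos.shape, start)
        else:
            breaks = np.sort(rng.uniform(1, length, size=n_break))
            src = (start + np.searchsorted(breaks, pos)) % 2
        idx = np.arange(lo, hi)
        child[lo:hi] = hap_pair[src, idx]
        corig[lo:hi] = orig_pair[src, idx]
    return child, corig


def gene_drop(
    pedigree: Pedigree, config: ColonyConfig, seed: int | None = None
) -> tuple[HaplotypeSet, GenotypeMatrix]:
    """Drop founder haplotypes through the pedigree with recombination.

    Crossover counts per meiosis per chromosome are Poisson with mean equal
    to the map length in Morgans (Haldane, no interference); breakpoint
    positions are uniform under a linear cM-bp map.  Returns the true
    phased haplotypes (with founder-origin labels) and the genotype matrix.
    """
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 0x5EED
    )
    sites = _draw_sites(config, rng)
    f_alleles, f_origins, causal_idx, disease_origin = _founder_haplotypes(
        config, sites, rng
    )

    order = pedigree.topological_order()
    ids = [i.iid for i in order]
    idx_of = {iid: k for k, iid in enumerate(ids)}
    n = len(ids)
    n_sites = len(sites)
    haps = np.zeros((n, 2, n_sites), dtype=np.int8)
    origins = np.zeros((n, 2, n_sites), dtype=np.int16)

    chrom_slices: list[tuple[int, int, np.ndarray, int, float]] = []
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    genome = {c: (length, cm) for c, length, cm in config.genome}
    start = 0
    while start < n_sites:
        c = chrom_arr[start]
        stop = start
        while stop < n_sites and chrom_arr[stop] == c:
            stop += 1
        length, cm = genome[c]
        chrom_slices.append((start, stop, pos_arr[start:stop], length, cm / 100.0))
        start = stop

    founder_slot = 0
    for ind in order:
        k = idx_of[ind.iid]
        if ind.is_founder:
            haps[k, 0] = f_alleles[founder_slot]
            haps[k, 1] = f_alleles[founder_slot + 1]
            origins[k, 0] = f_origins[founder_slot]
            origins[k, 1] = f_origins[founder_slot + 1]
            founder_slot += 2
        else:
            for side, parent in ((0, ind.sire), (1, ind.dam)):
                pk = idx_of[parent]
                haps[k, side], origins[k, side] = _meiosis(
                    haps[pk], origins[pk], chrom_slices, rng
                )

    dosage = haps.sum(axis=1).T.astype(np.int8)  # (n_sites, n_ind)
    phased = np.transpose(haps, (2, 0, 1)).copy()
    if config.dropout_prob > 0:
        drop = rng.random(dosage.shape) < config.dropout_prob
        dosage = dosage.copy()
        dosage[drop] = MISSING
    gm = GenotypeMatrix(sites.copy(), ids, dosage, phased)
    # GenotypeMatrix sorting must not reorder: sites are pre-sorted
    hs = HaplotypeSet(
        sites,
        ids,
        haps,
        origins,
        disease_origin,
        causal_idx,
        config.segment_bounds,
    )
    return hs, gm


def assign_phenotypes(pedigree: Pedigree, haplotypes: HaplotypeSet) -> Pedigree:
    """Fully penetrant recessive phenotypes from the causal-site genotype."""
    dos = haplotypes.causal_dosages()
    inds = [
        Individual(
            i.iid,
            i.sire,
            i.dam,
            i.sex,
            Phenotype.AFFECTED if dos[i.iid] == 2 else Phenotype.UNAFFECTED,
        )
        for i in pedigree
    ]
    return Pedigree(inds, family_id=pedigree.family_id)


# ---------------------------------------------------------------------------
# Marker panel
# ---------------------------------------------------------------------------

class PanelError(ValueError):
    """Not enough polymorphic sites in a panel stratum."""


def _evenly_spaced(
    positions: np.ndarray, candidates: np.ndarray, n: int, stratum: str
) -> np.ndarray:
    """Pick n candidate indices whose positions best match an even grid."""
    if n == 0:
        return np.array([], dtype=int)
    if len(candidates) < n:
        raise PanelError(
            f"insufficient polymorphic sites in {stratum} stratum: "
            f"have {len(candidates)}, need {n}"
        )
    targets = np.linspace(positions.min(), positions.max(), n)
    chosen: list[int] = []
    used = np.zeros(len(candidates), dtype=bool)
    for t in targets:
        d = np.abs(positions - t).astype(float)
        d[used] = np.inf
        j = int(np.argmin(d))
        used[j] = True
        chosen.append(int(candidates[j]))
    return np.array(sorted(chosen), dtype=int)


def extract_marker_panel(
    genotypes: GenotypeMatrix,
    spec: MarkerPanelSpec,
    interval: tuple[str, int, int],
    causal_chromosome: str | None = None,
) -> GenotypeMatrix:
    """Select an amplicon-style marker panel from a genotype matrix.

    Three strata: ``interval_markers`` evenly spaced within ``interval``
    (chrom, start, end, 1-based inclusive), ``chromosome_markers`` on the
    rest of that chromosome, and ``genomewide_markers`` spread across the
    remaining chromosomes.  Only polymorphic sites are eligible.
    """
    chrom, lo, hi = interval
    causal_chromosome = causal_chromosome or chrom
    called = genotypes.dosage != MISSING
    mn = np.where(called, genotypes.dosage, 3).min(axis=1)
    mx = np.where(called, genotypes.dosage, -2).max(axis=1)
    polymorphic = (mx > mn) & called.any(axis=1)

    site_chrom = genotypes.sites["chrom"].to_numpy()
    site_pos = genotypes.sites["pos"].to_numpy()
    in_interval = (site_chrom == chrom) & (site_pos >= lo) & (site_pos <= hi)

    strata = []
    cand = np.flatnonzero(polymorphic & in_interval)
    strata.append(_evenly_spaced(site_pos[cand], cand, spec.interval_markers, "interval"))
    cand = np.flatnonzero(polymorphic & (site_chrom == causal_chromosome) & ~in_interval)
    strata.append(
        _evenly_spaced(site_pos[cand], cand, spec.chromosome_markers, "chromosome")
    )
    cand = np.flatnonzero(polymorphic & (site_chrom != causal_chromosome))
    strata.append(
        _evenly_spaced(
            np.arange(len(cand)), cand, spec.genomewide_markers, "genome-wide"
        )
    )
    idx = np.sort(np.concatenate(strata)).astype(int)
    return genotypes.take_sites(idx)


# ---------------------------------------------------------------------------
# Simulated annotations for the candidate interval
# ---------------------------------------------------------------------------

def simulate_annotations(
    sites: pd.DataFrame,
    causal: tuple[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Annotation table for interval variants with a planted frameshift.

    The causal variant gets a frameshift consequence, an allele frequency
    absent from the population database, the highest CADD in the interval,
    and high tissue expression; the background receives mostly noncoding
    consequences, sub-threshold or absent allele frequencies, and low CADD.
    """
    rng = np.random.default_rng(seed + 0xA110)
    n = len(sites)
    chrom, pos = causal
    is_causal = (
        (sites["chrom"] == chrom) & (sites["pos"] == pos)
    ).to_numpy()
    consequence = rng.choice(
        ["noncoding", "synonymous", "missense"], size=n, p=[0.85, 0.10, 0.05]
    ).astype(object)
    af = rng.uniform(0.0, 0.10, size=n)
    af[rng.random(n) < 0.4] = np.nan  # private (absent from database)
    cadd = rng.uniform(0.0, 20.0, size=n)
    gerp = rng.uniform(-8.0, 6.0, size=n)
    cpm = np.round(rng.lognormal(mean=0.0, sigma=1.5, size=n), 1)
    liftover = rng.random(n) > 0.05

    consequence[is_causal] = "frameshift"
    af[is_causal] = np.nan
    cadd[is_causal] = rng.uniform(25.0, 35.0)
    gerp[is_causal] = 5.5
    cpm[is_causal] = rng.lognormal(mean=np.log(1000.0), sigma=0.1)
    liftover[is_causal] = True

    out = sites[["chrom", "pos", "ref", "alt"]].copy()
    out["consequence"] = consequence
    out["af_population"] = np.round(af, 4)
    out["cadd"] = np.round(cadd, 1)
    out["gerp"] = np.round(gerp, 1)
    out["cpm_tissue"] = np.round(cpm, 1)
    out["liftover_ok"] = liftover
    out.loc[~liftover, "cadd"] = np.nan
    out["cadd_basis_consequence"] = out["consequence"]
    return out


def default_colony(seed: int = 0, **overrides) -> ColonyConfig:
    """Convenience: the default study conditions with a chosen seed."""
    return replace(ColonyConfig(), seed=seed, **overrides)
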