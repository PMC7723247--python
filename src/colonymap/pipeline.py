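"""End-to-end mapping study on a synthetic colony.

Chains the pipeline stages the way the mapping study ran them: simulate a
colony, label a WGS-style subset (8 affected + 6 obligate carriers),
zygosity-filter genome-wide variants, test for clustering, fine-map the
critical interval inside the peak window, and rank candidate variants from
a (simulated) annotation table.  Used by the CLI ``run-all`` command, the
recovery tests and the examples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .expression import cpm_normalize, expression_reduction_test
from .expression_sim import ExpressionBundle, ExpressionSimConfig, simulate_expression
from .genotypes import GenotypeMatrix
from .linkage import CriticalInterval, delineate_critical_interval
from .pedigree import Pedigree
from .simulate import (
    ColonyConfig,
    HaplotypeSet,
    assign_phenotypes,
    extract_marker_panel,
    gene_drop,
    simulate_annotations,
    simulate_pedigree,
)
from .prioritize import filter_and_rank
from .zygosity import (
    ClusterTestResult,
    ZygosityFilterConfig,
    ZygosityResult,
    cluster_enrichment,
    zygosity_filter,
)

log = logging.getLogger(__name__)


@dataclass
class ColonyStudyResult:
    pedigree: Pedigree
    haplotypes: HaplotypeSet
    genotypes: GenotypeMatrix
    panel: GenotypeMatrix
    zygosity: ZygosityResult
    cluster: ClusterTestResult
    interval: CriticalInterval
    candidates: pd.DataFrame
    affected_labels: list[str]
    carrier_labels: list[str]

    @property
    def causal(self) -> tuple[str, int]:
        row = self.haplotypes.sites.iloc[self.haplotypes.causal_index]
        return str(row["chrom"]), int(row["pos"])

    @property
    def peak_contains_causal(self) -> bool:
        w = self.cluster.peak_window
        c, p = self.causal
        return w["chrom"] == c and w["start"] <= p <= w["end"]

    @property
    def interval_contains_causal(self) -> bool:
        return self.interval.found and self.interval.contains(*self.causal)

    @property
    def top_candidate_is_causal(self) -> bool:
        if self.candidates.empty:
            return False
        top = self.candidates.iloc[0]
        c, p = self.causal
        return top["chrom"] == c and int(top["pos"]) == p


def run_colony_study(
    config: ColonyConfig | None = None,
    seed: int | None = None,
    n_wgs_affected: int = 8,
    n_wgs_carriers: int = 6,
    window_size: int = 5_000_000,
) -> ColonyStudyResult:
    """Simulate one colony and run zygosity -> cluster -> interval -> ranking."""
    config = config or ColonyConfig()
    if seed is not None:
        config = ColonyConfig(**{**config.__dict__, "seed": seed})
    ped = simulate_pedigree(config)
    hapset, geno = gene_drop(ped, config)
    ped = assign_phenotypes(ped, hapset)

    dosages = hapset.causal_dosages()
    affected = sorted(ped.affected_ids())[:n_wgs_affected]
    carriers = [
        i for i in ped.obligate_carrier_ids() if dosages[i] == 1
    ]
    carriers = sorted(carriers)[:n_wgs_carriers]
    if not affected or not carriers:
        raise RuntimeError(
            f"colony (seed {config.seed}) lacks labeled individuals: "
            f"{len(affected)} affected, {len(carriers)} carriers"
        )
    n_labeled = len(affected) + len(carriers)
    zcfg = ZygosityFilterConfig(
        affected, carriers, min_called=max(1, n_labeled - 3)
    )
    zyg = zygosity_filter(geno, zcfg)
    genome = {c: length for c, length, _cm in config.genome}
    cluster = cluster_enrichment(
        zyg.passing_sites, genome, window_size=window_size, tested_sites=geno.sites
    )

    panel = extract_marker_panel(
        geno,
        config.marker_panel_spec,
        (config.causal_chromosome, *config.panel_interval),
    )

    # fine-map inside the peak window (plus one window of slack each side)
    peak = cluster.peak_window
    lo = max(1, int(peak["start"]) - window_size)
    hi = int(peak["end"]) + window_size
    chrom = str(peak["chrom"])
    idx = geno.sites_on(chrom)
    pos = geno.sites["pos"].to_numpy()[idx]
    fine = geno.take_sites(idx[(pos >= lo) & (pos <= hi)])
    # anchor fine-mapping at the zygosity signal inside the peak window
    pz = zyg.passing_sites
    in_peak = pz[
        (pz["chrom"] == chrom)
        & (pz["pos"] >= int(peak["start"]))
        & (pz["pos"] <= int(peak["end"]))
    ]
    anchor = int(in_peak["pos"].median()) if len(in_peak) else None
    interval = delineate_critical_interval(
        fine, sorted(ped.affected_ids()), chrom=chrom, anchor=anchor
    )

    if interval.found:
        sidx = geno.sites_on(interval.chrom)
        spos = geno.sites["pos"].to_numpy()[sidx]
        in_iv = sidx[(spos >= interval.outer_start) & (spos <= interval.outer_end)]
        interval_sites = geno.sites.iloc[in_iv].reset_index(drop=True)
    else:
        interval_sites = geno.sites.iloc[[]].copy()
    crow = hapset.sites.iloc[hapset.causal_index]
    ann = simulate_annotations(
        interval_sites, (str(crow["chrom"]), int(crow["pos"])), seed=config.seed
    )
    candidates = filter_and_rank(ann)
    return ColonyStudyResult(
        ped, hapset, geno, panel, zyg, cluster, interval, candidates,
        affected, carriers,
    )


def run_expression_study(
    result: ColonyStudyResult,
    config: ExpressionSimConfig | None = None,
    seed: int | None = None,
) -> tuple[ExpressionBundle, float]:
    """Simulate RNA-seq for the colony and measure the NMD reduction."""
    config = config or ExpressionSimConfig()
    bundle = simulate_expression(
        result.pedigree, result.haplotypes.causal_dosages(), config, seed=seed
    )
    cpm = cpm_normalize(bundle.counts, bundle.library_sizes)
    red = expression_reduction_test(cpm, bundle.groups, bundle.target_gene)
    return bundle, red.percent_reduction
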