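"""Zygosity mapping: recessive-compatible variant filtering and clustering.

A variant is compatible with a fully penetrant autosomal recessive model
when every called affected individual is homozygous for the alternate
allele and every called obligate carrier is heterozygous.  Compatible
variants are then tested for genomic clustering against a random
genome-wide distribution with a chi-square test over fixed windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class ZygosityFilterConfig:
    """Labeled individuals and the minimum-call rule.

    ``min_called`` is an absolute count over the labeled (affected +
    carrier) individuals; the default of 11 tolerates up to three missing
    calls in the canonical 8-affected + 6-carrier labeling.
    """

    affected_ids: list[str]
    carrier_ids: list[str]
    min_called: int = 11

    def __post_init__(self) -> None:
        if not self.affected_ids:
            raise ValueError("affected id set is empty")
        overlap = set(self.affected_ids) & set(self.carrier_ids)
        if overlap:
            raise ValueError(f"ids labeled both affected and carrier: {sorted(overlap)}")
        n = len(self.affected_ids) + len(self.carrier_ids)
        if self.min_called > n:
            raise ValueError(f"min_called {self.min_called} > {n} labeled individuals")


@dataclass
class ZygosityResult:
    passing_index: np.ndarray  # site indices into the input matrix
    passing_sites: pd.DataFrame
    called_counts: np.ndarray  # labeled individuals called, per site


def zygosity_filter(matrix: GenotypeMatrix, cfg: ZygosityFilterConfig) -> ZygosityResult:
    """Sites where all called affected are hom-alt and all called carriers het.

    A site fails outright if any called labeled genotype violates the
    model; missing calls are tolerated down to ``min_called`` labeled
    calls per site.
    """
    ai = matrix.sample_index(cfg.affected_ids)
    ci = matrix.sample_index(cfg.carrier_ids)
    aff = matrix.dosage[:, ai]
    car = matrix.dosage[:, ci]
    aff_called = aff != MISSING
    car_called = car != MISSING
    ok_aff = np.where(aff_called, aff == 2, True).all(axis=1)
    ok_car = np.where(car_called, car == 1, True).all(axis=1)
    n_called = aff_called.sum(axis=1) + car_called.sum(axis=1)
    passing = ok_aff & ok_car & (n_called >= cfg.min_called)
    idx = np.flatnonzero(passing)
    log.info(
        "zygosity_filter: %d/%d sites pass (%d affected, %d carriers, min_called=%d)",
        len(idx), matrix.n_sites, len(ai), len(ci), cfg.min_called,
    )
    return ZygosityResult(idx, matrix.sites.iloc[idx].reset_index(drop=True),
                          n_called)


@dataclass
class ClusterTestResult:
    windows: pd.DataFrame  # chrom, start, end, observed, expected, residual
    statistic: float
    df: int
    p_value: float

    @property
    def peak_window(self) -> pd.Series:
        return self.windows.loc[self.windows["residual"].idxmax()]


class NoPassingVariantsError(ValueError):
    """Cluster test requested with zero passing variants."""


def make_windows(
    genome: list[tuple[str, int]] | dict[str, int],
    window_size: int,
) -> pd.DataFrame:
    """Fixed windows over chromosomes (1-based inclusive).

    A trailing partial window shorter than half the window size is merged
    with the previous window to avoid small-expectation cells.
    """
    if isinstance(genome, dict):
        genome = list(genome.items())
    rows = []
    for chrom, length in genome:
        starts = list(range(1, length + 1, window_size))
        bounds = [(s, min(s + window_size - 1, length)) for s in starts]
        if len(bounds) > 1:
            last_lo, last_hi = bounds[-1]
            if last_hi - last_lo + 1 < window_size / 2:
                bounds[-2] = (bounds[-2][0], last_hi)
                bounds.pop()
        for lo, hi in bounds:
            rows.append((chrom, lo, hi))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def cluster_enrichment(
    passing_sites: pd.DataFrame,
    genome: list[tuple[str, int]] | dict[str, int],
    window_size: int = 5_000_000,
    null: str = "uniform",
    tested_sites: pd.DataFrame | None = None,
) -> ClusterTestResult:
    """Chi-square test of variant clustering vs. a random genome-wide null.

    The genome (chromosomes carrying at least one tested variant) is
    partitioned into fixed windows.  Under the default ``uniform`` null
    every window expects K / n_windows variants; the ``tested_density``
    null sets expectations proportional to the number of tested variants
    per window (requires ``tested_sites``).
    """
    if len(passing_sites) == 0:
        raise NoPassingVariantsError("no passing variants; cluster test undefined")
    if isinstance(genome, dict):
        genome = list(genome.items())
    present = set(
        (tested_sites if tested_sites is not None else passing_sites)["chrom"]
    )
    genome = [(c, length) for c, length in genome if c in present]
    windows = make_windows(genome, window_size)

    def _counts(sites: pd.DataFrame) -> np.ndarray:
        counts = np.zeros(len(windows), dtype=float)
        for w, row in enumerate(windows.itertuples(index=False)):
            hit = (
                (sites["chrom"] == row.chrom)
                & (sites["pos"] >= row.start)
                & (sites["pos"] <= row.end)
            )
            counts[w] = int(hit.sum())
        return counts

    observed = _counts(passing_sites)
    k = observed.sum()
    if null == "uniform":
        expected = np.full(len(windows), k / len(windows))
    elif null == "tested_density":
        if tested_sites is None:
            raise ValueError("tested_density null requires tested_sites")
        dens = _counts(tested_sites)
        if dens.sum() == 0:
            raise ValueError("tested_sites empty")
        expected = k * dens / dens.sum()
    else:
        raise ValueError(f"unknown null {null!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
        resid = np.where(
            expected > 0, (observed - expected) / np.sqrt(expected), 0.0
        )
    x2 = float(contrib.sum())
    dof = len(windows) - 1
    p = float(stats.chi2.sf(x2, dof))
    out = windows.copy()
    out["observed"] = observed
    out["expected"] = expected
    out["residual"] = resid
    log.info(
        "cluster_enrichment: K=%d over %d windows, X2=%.2f df=%d p=%.3g",
        int(k), len(windows), x2, dof, p,
    )
    return ClusterTestResult(out, x2, dof, p)


def two_locus_homref_count(
    n_total: int,
    n_nonref_a: int,
    n_nonref_b: int,
    n_both_nonref: int = 0,
) -> int:
    """Individuals homozygous reference at both of two unlinked loci.

    Inclusion-exclusion over per-locus non-reference (carrier or
    homozygous mutant) counts; ``n_both_nonref`` is the number carrying
    mutant alleles at both loci.
    """
    if min(n_total, n_nonref_a, n_nonref_b, n_both_nonref) < 0:
        raise ValueError("counts must be non-negative")
    out = n_total - n_nonref_a - n_nonref_b + n_both_nonref
    if out < 0:
        raise ValueError("inconsistent counts")
    return out
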