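"""Genotype matrix container: sites x samples alt-allele dosages.

Dosages are stored as int8 with -1 denoting a missing call.  Sites are kept
strictly sorted by (chromosome, position); coordinates are 1-based inclusive
throughout the package (VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Alt-allele dosage matrix over ordered biallelic sites.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom, pos, ref, alt`` (1-based positions).
    samples
        Ordered sample ids.
    dosage
        ``(n_sites, n_samples)`` int8 array with values in {0, 1, 2, -1}.
    """

    sites: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray
    phased: np.ndarray | None = field(default=None, repr=False)
    # optional (n_sites, n_samples, 2) haplotype alleles backing phased output

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if list(self.sites.columns[:4]) != SITE_COLUMNS:
            missing = [c for c in SITE_COLUMNS if c not in self.sites.columns]
            if missing:
                raise ValueError(f"sites table missing columns {missing}")
        if self.dosage.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.sites)}, {len(self.samples)})"
            )
        bad = ~np.isin(self.dosage, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError(f"invalid dosage values: {np.unique(self.dosage[bad])}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        self._sort_sites()
        self._sample_idx = {s: j for j, s in enumerate(self.samples)}

    def _sort_sites(self) -> None:
        order = self.sites.sort_values(["chrom", "pos", "alt"], kind="mergesort").index
        if not np.array_equal(order.to_numpy(), np.arange(len(self.sites))):
            self.sites = self.sites.loc[order].reset_index(drop=True)
            self.dosage = self.dosage[order.to_numpy()]
            if self.phased is not None:
                self.phased = self.phased[order.to_numpy()]
        key = self.sites[["chrom", "pos", "alt"]]
        if key.duplicated().any():
            dups = key[key.duplicated()].to_records(index=False).tolist()
            raise ValueError(f"duplicate sites: {dups[:5]}")

    # -- views ---------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, ids: list[str]) -> np.ndarray:
        unknown = [s for s in ids if s not in self._sample_idx]
        if unknown:
            raise KeyError(f"unknown sample ids: {unknown}")
        return np.array([self._sample_idx[s] for s in ids], dtype=int)

    def dosage_of(self, sample: str) -> np.ndarray:
        return self.dosage[:, self.sample_index([sample])[0]]

    def called_mask(self) -> np.ndarray:
        return self.dosage != MISSING

    # -- subsetting ----------------------------------------------------------
    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            self.sites.iloc[idx].reset_index(drop=True),
            list(self.samples),
            self.dosage[idx],
            None if self.phased is None else self.phased[idx],
        )

    def take_samples(self, ids: list[str]) -> "GenotypeMatrix":
        j = self.sample_index(ids)
        return GenotypeMatrix(
            self.sites.copy(),
            list(ids),
            self.dosage[:, j],
            None if self.phased is None else self.phased[:, j],
        )

    def sites_on(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.sites["chrom"] == chrom).to_numpy())

    def site_index(self, chrom: str, pos: int) -> int:
        hit = np.flatnonzero(
            ((self.sites["chrom"] == chrom) & (self.sites["pos"] == pos)).to_numpy()
        )
        if len(hit) == 0:
            raise KeyError(f"no site at {chrom}:{pos}")
        return int(hit[0])

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.sites[SITE_COLUMNS].equals(other.sites[SITE_COLUMNS])
            and np.array_equal(self.dosage, other.dosage)
        )
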