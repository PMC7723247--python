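"""Shared fixtures: small study configurations and canonical pedigrees."""

from __future__ import annotations

import numpy as np
import pytest

import colonymap as cm
from colonymap.pedigree import Individual, Pedigree, Phenotype, Sex

# A reduced genome keeps unit tests fast while preserving the structure the
# pipeline needs (several chromosomes, a causal chromosome with an embedded
# IBD segment).
SMALL_GENOME = (
    ("chr1", 30_000_000, 30.0),
    ("chr2", 30_000_000, 30.0),
    ("chr3", 40_000_000, 40.0),
)


def small_config(seed: int = 0, **overrides) -> cm.ColonyConfig:
    defaults = dict(
        n_founders=8,
        n_generations=4,
        target_colony_size=60,
        genome=SMALL_GENOME,
        causal_chromosome="chr3",
        causal_position=25_000_000,
        panel_interval=(10_000_001, 40_000_000),
        variant_density=4.0,
        marker_panel_spec=cm.MarkerPanelSpec(12, 4, 10),
        seed=seed,
    )
    defaults.update(overrides)
    return cm.ColonyConfig(**defaults)


@pytest.fixture(scope="session")
def small_cfg() -> cm.ColonyConfig:
    return small_config(seed=0)


@pytest.fixture(scope="session")
def small_colony(small_cfg):
    ped = cm.simulate_pedigree(small_cfg)
    hapset, geno = cm.gene_drop(ped, small_cfg)
    ped = cm.assign_phenotypes(ped, hapset)
    return ped, hapset, geno


def carrier_x_carrier_family(n_affected: int) -> Pedigree:
    """Two unaffected parents, n affected children (obligate carriers)."""
    inds = [
        Individual("SIRE", sex=Sex.MALE, phenotype=Phenotype.UNAFFECTED),
        Individual("DAM", sex=Sex.FEMALE, phenotype=Phenotype.UNAFFECTED),
    ]
    for i in range(n_affected):
        inds.append(
            Individual(f"KID{i}", "SIRE", "DAM", Sex.MALE, Phenotype.AFFECTED)
        )
    return Pedigree(inds)


def random_small_pedigree(rng: np.random.Generator):
    """5-8 members (<= 5 meioses): fodder for the LOD equivalence sweep."""
    inds = [Individual("F0", sex=Sex.MALE), Individual("M0", sex=Sex.FEMALE)]
    n_kids = int(rng.integers(2, 4))
    for i in range(n_kids):
        inds.append(
            Individual(
                f"K{i}", "F0", "M0", Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
            )
        )
    if rng.random() < 0.5:
        inds[2].sex = Sex.MALE
        inds.append(Individual("S0", sex=Sex.FEMALE))
        inds.append(Individual("G0", "K0", "S0", Sex.MALE))
    ped = Pedigree(inds)
    for ind in ped:
        ind.phenotype = rng.choice(
            [Phenotype.AFFECTED, Phenotype.UNAFFECTED, Phenotype.UNKNOWN],
            p=[0.3, 0.55, 0.15],
        )
    genotypes = {}
    for ind in ped:
        if rng.random() < 0.85:
            genotypes[ind.iid] = (int(rng.integers(2)), int(rng.integers(2)))
    return ped, genotypes


def het_group_series():
    import pandas as pd

    idx = (
        [f"A{i}" for i in range(4)]
        + [f"H{i}" for i in range(3)]
        + [f"R{i}" for i in range(3)]
    )
    return pd.Series(
        ["hom_mutant"] * 4 + ["het"] * 3 + ["hom_ref"] * 3, index=idx, name="group"
    )


def default_dosages():
    return (
        {f"A{i}": 2 for i in range(4)}
        | {f"H{i}": 1 for i in range(3)}
        | {f"R{i}": 0 for i in range(3)}
    )
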