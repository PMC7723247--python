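"""Pedigree structure for a closed breeding colony.

A pedigree is a directed acyclic family graph: every individual either has
both parents in the pedigree (non-founder) or neither (founder).  Phenotypes
follow the LINKAGE convention (affected / unaffected / unknown).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator


class Sex(Enum):
    MALE = 1
    FEMALE = 2


class Phenotype(Enum):
    UNKNOWN = 0
    UNAFFECTED = 1
    AFFECTED = 2


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, missing parent, ...)."""


@dataclass
class Individual:
    iid: str
    sire: str | None = None
    dam: str | None = None
    sex: Sex = Sex.MALE
    phenotype: Phenotype = Phenotype.UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.sire is None and self.dam is None


@dataclass
class Pedigree:
    """An ordered collection of individuals with parent links.

    Validation enforces: both parents present or both absent, referenced
    parents exist and have opposite sexes, and ancestry is acyclic.
    """

    individuals: list[Individual] = field(default_factory=list)
    family_id: str = "COLONY"

    def __post_init__(self) -> None:
        self._by_id = {ind.iid: ind for ind in self.individuals}
        if len(self._by_id) != len(self.individuals):
            seen: set[str] = set()
            dups = [i.iid for i in self.individuals if i.iid in seen or seen.add(i.iid)]
            raise PedigreeError(f"duplicate individual ids: {sorted(set(dups))}")
        self.validate()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def __getitem__(self, iid: str) -> Individual:
        return self._by_id[iid]

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        bad_half = [i.iid for i in self if (i.sire is None) != (i.dam is None)]
        if bad_half:
            raise PedigreeError(f"individuals with exactly one parent: {bad_half}")
        missing = [
            i.iid
            for i in self
            if not i.is_founder and (i.sire not in self._by_id or i.dam not in self._by_id)
        ]
        if missing:
            raise PedigreeError(f"individuals referencing absent parents: {missing}")
        bad_sex = [
            i.iid
            for i in self
            if not i.is_founder
            and (self._by_id[i.sire].sex != Sex.MALE or self._by_id[i.dam].sex != Sex.FEMALE)
        ]
        if bad_sex:
            raise PedigreeError(f"parents with inconsistent sexes for: {bad_sex}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        for start in self._by_id:
            if start in state:
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            while stack:
                iid, phase = stack.pop()
                if phase == 0:
                    if state.get(iid) == 0:
                        raise PedigreeError(f"cycle in ancestry involving {iid}")
                    if state.get(iid) == 1:
                        continue
                    state[iid] = 0
                    stack.append((iid, 1))
                    ind = self._by_id[iid]
                    for p in (ind.sire, ind.dam):
                        if p is not None and state.get(p) != 1:
                            stack.append((p, 0))
                else:
                    state[iid] = 1

    # -- convenience views ---------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [i.iid for i in self.individuals]

    def founders(self) -> list[Individual]:
        return [i for i in self if i.is_founder]

    def nonfounders(self) -> list[Individual]:
        return [i for i in self if not i.is_founder]

    def affected_ids(self) -> list[str]:
        return [i.iid for i in self if i.phenotype is Phenotype.AFFECTED]

    def children_of(self, iid: str) -> list[Individual]:
        return [i for i in self if iid in (i.sire, i.dam)]

    def topological_order(self) -> list[Individual]:
        """Individuals ordered parents-before-children."""
        order: list[Individual] = []
        placed: set[str] = set()
        pending = list(self.individuals)
        while pending:
            rest = []
            for ind in pending:
                if ind.is_founder or (ind.sire in placed and ind.dam in placed):
                    order.append(ind)
                    placed.add(ind.iid)
                else:
                    rest.append(ind)
            if len(rest) == len(pending):  # pragma: no cover - guarded by validate()
                raise PedigreeError("cannot order pedigree (cycle?)")
            pending = rest
        return order

    def obligate_carrier_ids(self) -> list[str]:
        """Unaffected parents of affected individuals.

        Under a fully penetrant recessive model such parents must be
        heterozygous for the disease allele.
        """
        carriers: list[str] = []
        for ind in self:
            if ind.phenotype is not Phenotype.AFFECTED:
                continue
            for p in (ind.sire, ind.dam):
                if p is not None and self._by_id[p].phenotype is not Phenotype.AFFECTED:
                    if p not in carriers:
                        carriers.append(p)
        return carriers

    def nuclear_families(self) -> list[tuple[str, str, list[str]]]:
        """(sire, dam, children) triples for every mated pair."""
        fams: dict[tuple[str, str], list[str]] = {}
        for ind in self:
            if not ind.is_founder:
                fams.setdefault((ind.sire, ind.dam), []).append(ind.iid)
        return [(s, d, kids) for (s, d), kids in sorted(fams.items())]

    def subset(self, ids: Iterable[str]) -> "Pedigree":
        """Sub-pedigree on `ids`; parents outside the set become founders."""
        keep = set(ids)
        subs = []
        for iid in ids:
            ind = self._by_id[iid]
            sire = ind.sire if ind.sire in keep else None
            dam = ind.dam if ind.dam in keep else None
            if (sire is None) != (dam is None):
                sire = dam = None
            subs.append(Individual(ind.iid, sire, dam, ind.sex, ind.phenotype))
        return Pedigree(subs, family_id=self.family_id)
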