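"""Parametric two-point linkage, diplotype reconstruction, critical interval.

The likelihood of a pedigree at a single marker linked to the disease
locus at recombination fraction theta is summed exactly over founder
phased two-locus diplotypes (HWE priors, linkage equilibrium) and
per-meiosis transmission/recombination outcomes:

    L(theta) = sum_founders prod P(diplotype)
               sum_meioses prod P(transmission; theta)
               prod_i penetrance_i * 1[marker genotype observed_i]

and LOD = log10 L(0) - log10 L(0.5).  The main implementation performs the
sum by variable elimination over per-individual phased two-locus states,
which is exact on looped pedigrees, under an explicit state budget; a
literal brute-force enumeration oracle is provided for verification.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .pedigree import Pedigree, Phenotype
from .simulate import HaplotypeSet

log = logging.getLogger(__name__)

MarkerGenotypes = dict[str, tuple[int, int] | None]


@dataclass
class DiseaseModel:
    """Rare fully penetrant recessive disease model.

    ``q`` is the disease allele frequency; ``penetrance`` gives
    P(affected | copies of the disease allele).
    """

    q: float = 0.001
    penetrance: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.q < 1.0):
            raise ValueError("disease allele frequency must be in (0, 1)")
        if any(not (0.0 <= f <= 1.0) for f in self.penetrance):
            raise ValueError("penetrances must be in [0, 1]")


@dataclass
class LodResult:
    lod: float
    informative: bool
    impossible_at_theta0: bool = False


class PedigreeTooLargeError(RuntimeError):
    """Exact likelihood exceeds the state budget."""


class MendelianImpossibleError(ValueError):
    """Marker genotypes impossible on this pedigree at any theta."""


# ---------------------------------------------------------------------------
# State machinery
# ---------------------------------------------------------------------------

def _state_tables(k: int) -> dict[str, np.ndarray]:
    """Decompose state s = (h1, h2), h = d*k + m, into component arrays."""
    H = 2 * k
    S = H * H
    s = np.arange(S)
    h1, h2 = s // H, s % H
    return {
        "H": H,
        "S": S,
        "h1": h1,
        "h2": h2,
        "d1": h1 // k,
        "m1": h1 % k,
        "d2": h2 // k,
        "m2": h2 % k,
    }


def _transmission(k: int, theta: float) -> np.ndarray:
    """T[h', s]: P(transmit haplotype h' | parent state s)."""
    t = _state_tables(k)
    H, S = t["H"], t["S"]
    T = np.zeros((H, S))
    dp = np.arange(H) // k
    mp = np.arange(H) % k
    for which, (d, m_same, m_other) in enumerate(
        [(t["d1"], t["m1"], t["m2"]), (t["d2"], t["m2"], t["m1"])]
    ):
        d_ok = dp[:, None] == d[None, :]
        T += 0.5 * d_ok * (
            (1 - theta) * (mp[:, None] == m_same[None, :])
            + theta * (mp[:, None] == m_other[None, :])
        )
    return T


def _founder_prior(k: int, q: float, allele_freqs: np.ndarray) -> np.ndarray:
    t = _state_tables(k)
    pd_ = np.array([1 - q, q])
    hap = pd_[np.arange(2 * k) // k] * allele_freqs[np.arange(2 * k) % k]
    return hap[t["h1"]] * hap[t["h2"]]


def _evidence(
    k: int,
    phenotype: Phenotype,
    observed: tuple[int, int] | None,
    model: DiseaseModel,
) -> np.ndarray:
    t = _state_tables(k)
    n_dis = t["d1"] + t["d2"]
    f = np.asarray(model.penetrance)[n_dis]
    if phenotype is Phenotype.AFFECTED:
        pen = f
    elif phenotype is Phenotype.UNAFFECTED:
        pen = 1.0 - f
    else:
        pen = np.ones_like(f)
    if observed is None:
        ind = np.ones(t["S"])
    else:
        a, b = sorted(observed)
        lo = np.minimum(t["m1"], t["m2"])
        hi = np.maximum(t["m1"], t["m2"])
        ind = ((lo == a) & (hi == b)).astype(float)
    return pen * ind


# ---------------------------------------------------------------------------
# Variable elimination
# ---------------------------------------------------------------------------

def _eliminate(
    factors: list[tuple[tuple[str, ...], np.ndarray]],
    S: int,
    budget: int,
) -> float:
    """Sum-product elimination of all variables; returns log10 of the sum.

    Factors are (vars, array) with one axis of size S per variable.
    Greedy minimum-intermediate-size ordering; each intermediate is
    rescaled to keep values in range, accumulating log10 scale.
    """
    log10_scale = 0.0
    factors = list(factors)
    variables = sorted({v for vs, _ in factors for v in vs})
    while variables:
        best_v, best_union = None, None
        for v in variables:
            union: list[str] = []
            for vs, _ in factors:
                if v in vs:
                    union.extend(x for x in vs if x not in union)
            if best_union is None or len(union) < len(best_union):
                best_v, best_union = v, union
        if S ** len(best_union) > budget:
            raise PedigreeTooLargeError(
                f"elimination cluster of {len(best_union)} individuals exceeds the "
                f"state budget ({S ** len(best_union)} > {budget}); split the "
                "pedigree into nuclear families (see sum_nuclear_family_lods)"
            )
        involved = [f for f in factors if best_v in f[0]]
        rest = [f for f in factors if best_v not in f[0]]
        prod = np.ones((S,) * len(best_union))
        for vs, arr in involved:
            shape = [S if u in vs else 1 for u in best_union]
            order = [vs.index(u) for u in best_union if u in vs]
            prod = prod * arr.transpose(order).reshape(shape)
        axis = best_union.index(best_v)
        summed = prod.sum(axis=axis)
        new_vars = tuple(u for u in best_union if u != best_v)
        peak = summed.max()
        if peak > 0:
            summed = summed / peak
            log10_scale += np.log10(peak)
        else:
            return -np.inf
        factors = rest + [(new_vars, summed)]
        variables.remove(best_v)
    total = 1.0
    for _, arr in factors:
        total *= float(arr)
    if total <= 0:
        return -np.inf
    return float(np.log10(total) + log10_scale)


def _build_factors(
    pedigree: Pedigree,
    genotypes: MarkerGenotypes,
    model: DiseaseModel,
    theta: float,
    k: int,
    allele_freqs: np.ndarray,
) -> list[tuple[tuple[str, ...], np.ndarray]]:
    t = _state_tables(k)
    S, H = t["S"], t["H"]
    T = _transmission(k, theta)
    prior = _founder_prior(k, model.q, allele_freqs)
    # child factor C[sc, sf, sm] = T[h1(sc), sf] * T[h2(sc), sm]
    C = T[t["h1"], :][:, :, None] * T[t["h2"], :][:, None, :]
    factors: list[tuple[tuple[str, ...], np.ndarray]] = []
    for ind in pedigree:
        e = _evidence(k, ind.phenotype, genotypes.get(ind.iid), model)
        if ind.is_founder:
            factors.append(((ind.iid,), prior * e))
        else:
            factors.append(
                ((ind.iid, ind.sire, ind.dam), C * e[:, None, None])
            )
    return factors


def _marker_setup(
    genotypes: MarkerGenotypes,
    n_alleles: int | None,
    allele_freqs: np.ndarray | None,
) -> tuple[int, np.ndarray]:
    observed = [g for g in genotypes.values() if g is not None]
    k = n_alleles or max((max(g) for g in observed), default=0) + 1
    k = max(k, 2)
    if allele_freqs is None:
        freqs = np.full(k, 1.0 / k)
    else:
        freqs = np.asarray(allele_freqs, dtype=float)
        if len(freqs) != k or not np.isclose(freqs.sum(), 1.0):
            raise ValueError("allele_freqs must have length n_alleles and sum to 1")
    return k, freqs


def _informative(genotypes: MarkerGenotypes) -> bool:
    observed = [tuple(sorted(g)) for g in genotypes.values() if g is not None]
    if not observed:
        return False
    het = any(a != b for a, b in observed)
    return het or len(set(observed)) > 1


def two_point_lod(
    pedigree: Pedigree,
    genotypes: MarkerGenotypes,
    model: DiseaseModel | None = None,
    n_alleles: int | None = None,
    allele_freqs: np.ndarray | None = None,
    budget: int = 20_000_000,
) -> LodResult:
    """Exact single-marker parametric LOD: log10 L(0) - log10 L(0.5).

    Marker genotypes map individual id to an unordered allele-index pair
    (``None`` / absent = untyped).  Marker allele frequencies default to
    equal.  Raises :class:`PedigreeTooLargeError` when exact elimination
    would exceed ``budget`` states rather than approximating.
    """
    model = model or DiseaseModel()
    k, freqs = _marker_setup(genotypes, n_alleles, allele_freqs)
    S = (2 * k) ** 2
    logs = {}
    for theta in (0.0, 0.5):
        factors = _build_factors(pedigree, genotypes, model, theta, k, freqs)
        logs[theta] = _eliminate(factors, S, budget)
    if not np.isfinite(logs[0.5]):
        raise MendelianImpossibleError(
            "marker genotypes are impossible on this pedigree (L(0.5) = 0)"
        )
    if not np.isfinite(logs[0.0]):
        return LodResult(-np.inf, _informative(genotypes), impossible_at_theta0=True)
    return LodResult(logs[0.0] - logs[0.5], _informative(genotypes))


# ---------------------------------------------------------------------------
# Brute-force enumeration oracle
# ---------------------------------------------------------------------------

def lod_enumeration_oracle(
    pedigree: Pedigree,
    genotypes: MarkerGenotypes,
    model: DiseaseModel | None = None,
    n_alleles: int | None = None,
    allele_freqs: np.ndarray | None = None,
    max_meioses: int = 10,
) -> LodResult:
    """Literal sum over founder diplotypes and per-meiosis outcomes.

    Exponential in pedigree size; refuses pedigrees with more than
    ``max_meioses`` meioses.  Used to verify :func:`two_point_lod`.
    """
    model = model or DiseaseModel()
    nonfounders = pedigree.nonfounders()
    if 2 * len(nonfounders) > max_meioses:
        raise PedigreeTooLargeError(
            f"{2 * len(nonfounders)} meioses exceed oracle limit {max_meioses}"
        )
    k, freqs = _marker_setup(genotypes, n_alleles, allele_freqs)
    t = _state_tables(k)
    H, S = t["H"], t["S"]
    prior = _founder_prior(k, model.q, freqs)
    evid = {
        ind.iid: _evidence(k, ind.phenotype, genotypes.get(ind.iid), model)
        for ind in pedigree
    }
    founders = [i.iid for i in pedigree.founders()]
    order = [i for i in pedigree.topological_order() if not i.is_founder]

    # transmitted haplotype per (parent state, outcome); outcome = (i, r):
    # disease allele from hap i, marker from hap i (r=0) or the other (r=1)
    trans = np.zeros((S, 4), dtype=np.int64)
    for o, (i, r) in enumerate(itertools.product((0, 1), (0, 1))):
        d = t["d1"] if i == 0 else t["d2"]
        m_from = (i + r) % 2
        m = t["m1"] if m_from == 0 else t["m2"]
        trans[:, o] = d * k + m

    founder_states = [np.flatnonzero(prior * evid[f] > 0) for f in founders]

    def likelihood(theta: float) -> float:
        # outcome o=(i,r) -> prob 0.5 * (theta if r else 1-theta)
        w_out = np.array(
            [0.5 * ((1 - theta) if r == 0 else theta)
             for i, r in itertools.product((0, 1), (0, 1))]
        )
        total = 0.0
        for combo in itertools.product(*founder_states):
            base = 1.0
            for f, s in zip(founders, combo):
                base *= prior[s] * evid[f][s]
            states = {f: np.array([s]) for f, s in zip(founders, combo)}
            w = np.array([base])
            for ind in order:
                L = len(w)
                o_p = np.tile(np.repeat(np.arange(4), 4), L)
                o_m = np.tile(np.tile(np.arange(4), 4), L)
                for key in states:
                    states[key] = np.repeat(states[key], 16)
                w = np.repeat(w, 16) * w_out[o_p] * w_out[o_m]
                hp = trans[states[ind.sire], o_p]
                hm = trans[states[ind.dam], o_m]
                sc = hp * H + hm
                w = w * evid[ind.iid][sc]
                keep = w > 0
                w = w[keep]
                for key in states:
                    states[key] = states[key][keep]
                sc = sc[keep]
                states[ind.iid] = sc
            total += float(w.sum())
        return total

    l0, l5 = likelihood(0.0), likelihood(0.5)
    if l5 <= 0:
        raise MendelianImpossibleError("L(0.5) = 0 in enumeration oracle")
    if l0 <= 0:
        return LodResult(-np.inf, _informative(genotypes), impossible_at_theta0=True)
    return LodResult(float(np.log10(l0) - np.log10(l5)), _informative(genotypes))


# ---------------------------------------------------------------------------
# Scans and decomposition
# ---------------------------------------------------------------------------

def genotypes_from_matrix(matrix: GenotypeMatrix, site_idx: int) -> MarkerGenotypes:
    """Biallelic dosages at one site as unordered allele pairs."""
    to_pair = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    out: MarkerGenotypes = {}
    for j, iid in enumerate(matrix.samples):
        d = int(matrix.dosage[site_idx, j])
        out[iid] = None if d == MISSING else to_pair[d]
    return out


def lod_scan(
    pedigree: Pedigree,
    panel: GenotypeMatrix,
    model: DiseaseModel | None = None,
    budget: int = 20_000_000,
    decompose: bool = False,
) -> pd.DataFrame:
    """Per-marker two-point LOD over a panel (S3-table-style layout).

    With ``decompose=True`` the pedigree is split into nuclear families and
    per-family LODs are summed (the standard fallback when the full
    pedigree exceeds the exact-likelihood budget).
    """
    model = model or DiseaseModel()
    rows = []
    for s in range(panel.n_sites):
        gt = genotypes_from_matrix(panel, s)
        gt = {i: g for i, g in gt.items() if i in pedigree}
        if decompose:
            res = sum_nuclear_family_lods(pedigree, gt, model, budget=budget)
        else:
            res = two_point_lod(pedigree, gt, model, budget=budget)
        site = panel.sites.iloc[s]
        rows.append(
            {
                "chrom": site["chrom"],
                "pos": int(site["pos"]),
                "lod": res.lod,
                "informative": res.informative,
                "impossible_at_theta0": res.impossible_at_theta0,
            }
        )
    return pd.DataFrame(rows)


def sum_nuclear_family_lods(
    pedigree: Pedigree,
    genotypes: MarkerGenotypes,
    model: DiseaseModel | None = None,
    budget: int = 20_000_000,
) -> LodResult:
    """Sum of independent nuclear-family LODs (loop-free decomposition)."""
    model = model or DiseaseModel()
    total = 0.0
    informative = False
    impossible = False
    for sire, dam, kids in pedigree.nuclear_families():
        fam = pedigree.subset([sire, dam] + kids)
        fam_gt = {i: genotypes.get(i) for i in fam.ids}
        try:
            res = two_point_lod(fam, fam_gt, model, budget=budget)
        except MendelianImpossibleError:
            log.warning("skipping Mendelian-inconsistent family (%s x %s)", sire, dam)
            continue
        informative = informative or res.informative
        if res.impossible_at_theta0:
            impossible = True
            total = -np.inf
        elif np.isfinite(total):
            total += res.lod
    return LodResult(total, informative, impossible)


# ---------------------------------------------------------------------------
# Diplotype reconstruction
# ---------------------------------------------------------------------------

UNCERTAIN = np.int8(-1)


@dataclass
class Diplotype:
    iid: str
    hap_paternal: np.ndarray  # allele per marker, -1 uncertain
    hap_maternal: np.ndarray
    imputed: bool = False


def reconstruct_diplotypes(
    pedigree: Pedigree, panel: GenotypeMatrix
) -> tuple[list[Diplotype], list[tuple[str, str, int]]]:
    """Rule-based phasing of a marker panel through the pedigree.

    Phase is assigned only where Mendelian transmission forces it
    (homozygous child; homozygous parent resolving a het child); untyped
    parents are imputed from a genotyped mate and progeny (the transmitted
    haplotype equals the child haplotype not attributable to the mate),
    with the second haplotype left uncertain.  Positions that cannot be
    resolved are marked uncertain, never guessed.  Returns the diplotypes
    plus a list of (iid, marker chrom:pos, site index) Mendelian conflicts
    (those markers are excluded for the family).
    """
    n = panel.n_sites
    geno = {
        iid: panel.dosage[:, j].copy() for j, iid in enumerate(panel.samples)
    }
    blank = np.full(n, MISSING, dtype=np.int8)
    conflicts: list[tuple[str, str, int]] = []
    conflict_sites: dict[str, set[int]] = {}

    haps: dict[str, np.ndarray] = {
        ind.iid: np.full((2, n), UNCERTAIN, dtype=np.int8) for ind in pedigree
    }
    imputed = {
        ind.iid: (ind.iid not in geno) or bool((geno[ind.iid] == MISSING).all())
        for ind in pedigree
    }

    def possible(parent_g: int) -> set[int]:
        return {0: {0}, 1: {0, 1}, 2: {1}, -1: {0, 1}}[int(parent_g)]

    # pass 1: trio-forced phase for genotyped non-founders
    for ind in pedigree.nonfounders():
        g_c = geno.get(ind.iid, blank)
        g_f = geno.get(ind.sire, blank)
        g_m = geno.get(ind.dam, blank)
        for s in range(n):
            gc = int(g_c[s])
            if gc == MISSING:
                continue
            pf, pm = possible(g_f[s]), possible(g_m[s])
            label = f"{panel.sites.iloc[s]['chrom']}:{panel.sites.iloc[s]['pos']}"
            if gc == 0 or gc == 2:
                a = 0 if gc == 0 else 1
                if a not in pf or a not in pm:
                    conflicts.append((ind.iid, label, s))
                    conflict_sites.setdefault(ind.iid, set()).add(s)
                    continue
                haps[ind.iid][0, s] = a
                haps[ind.iid][1, s] = a
            else:  # het child
                options = [(a, 1 - a) for a in (0, 1) if a in pf and (1 - a) in pm]
                if not options:
                    conflicts.append((ind.iid, label, s))
                    conflict_sites.setdefault(ind.iid, set()).add(s)
                elif len(options) == 1:
                    haps[ind.iid][0, s], haps[ind.iid][1, s] = options[0]

    # pass 2: founder / untyped-parent haplotypes from progeny
    for ind in pedigree:
        target = haps[ind.iid]
        g_self = geno.get(ind.iid, blank)
        if not imputed[ind.iid]:
            # genotyped: homozygous markers self-phase (except flagged
            # Mendelian conflicts, which stay excluded for the family)
            hom = (g_self == 0) | (g_self == 2)
            for s_bad in conflict_sites.get(ind.iid, ()):
                hom[s_bad] = False
            target[0, hom] = (g_self[hom] == 2).astype(np.int8)
            target[1, hom] = target[0, hom]
        if ind.is_founder or imputed[ind.iid]:
            # impute the transmitted haplotype from a single child (merging
            # across children would chimerize distinct recombinant gametes);
            # it may itself be a recombinant mosaic of the two true
            # haplotypes, which is all progeny data can reveal
            kids = sorted(pedigree.children_of(ind.iid), key=lambda x: x.iid)
            best_child, best_known = None, 0
            for child in kids:
                side = 0 if child.sire == ind.iid else 1
                known = int((haps[child.iid][side] != UNCERTAIN).sum())
                if known > best_known:
                    best_child, best_known = (child, side), known
            if best_child is not None:
                child, side = best_child
                ch = haps[child.iid][side]
                known = ch != UNCERTAIN
                fill = known & (target[0] == UNCERTAIN)
                target[0, fill] = ch[fill]
            # complement where own genotype known
            g_known = (g_self != MISSING) & (target[0] != UNCERTAIN)
            comp = g_self[g_known] - target[0, g_known]
            valid = (comp >= 0) & (comp <= 1)
            idx = np.flatnonzero(g_known)[valid]
            target[1, idx] = (g_self[idx] - target[0, idx]).astype(np.int8)

    out = [
        Diplotype(ind.iid, haps[ind.iid][0], haps[ind.iid][1], imputed[ind.iid])
        for ind in pedigree
    ]
    if conflicts:
        log.warning("reconstruct_diplotypes: %d Mendelian conflicts", len(conflicts))
    return out, conflicts


# ---------------------------------------------------------------------------
# Critical interval
# ---------------------------------------------------------------------------

@dataclass
class CriticalInterval:
    chrom: str
    inner_start: int
    inner_end: int
    outer_start: int
    outer_end: int
    marker_index: np.ndarray  # panel site indices in the run
    found: bool = True

    @property
    def inner_span(self) -> int:
        return self.inner_end - self.inner_start + 1

    @property
    def outer_span(self) -> int:
        return self.outer_end - self.outer_start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.outer_start <= pos <= self.outer_end


def delineate_critical_interval(
    panel: GenotypeMatrix,
    affected_ids: list[str],
    chrom: str | None = None,
    anchor: int | None = None,
) -> CriticalInterval:
    """Marker run over which every affected is homozygous for one shared allele.

    The disease-haplotype allele at each marker is the consensus allele for
    which all called affected individuals are homozygous; candidate
    intervals are contiguous runs of such markers.  Without an ``anchor``
    the longest run is returned (per chromosome; the best chromosome is
    chosen unless ``chrom`` is given).  With an ``anchor`` position (e.g.
    the zygosity-mapping peak), the run nearest the anchor on that
    chromosome is returned — the fine-mapping use case, robust to chance
    shared-homozygosity runs elsewhere.  Inner bounds are the first/last
    run markers; outer bounds extend to the nearest flanking markers
    violating the condition (or the panel ends).
    """
    if anchor is not None and chrom is None:
        raise ValueError("anchor requires chrom")
    aff = panel.take_samples(affected_ids)
    best: CriticalInterval | None = None
    best_key: tuple | None = None
    chroms = [chrom] if chrom else list(pd.unique(panel.sites["chrom"]))
    for c in chroms:
        idx = panel.sites_on(c)
        if len(idx) == 0:
            continue
        d = aff.dosage[idx]
        called = d != MISSING
        any_called = called.any(axis=1)
        all_hom0 = np.where(called, d == 0, True).all(axis=1) & any_called
        all_hom2 = np.where(called, d == 2, True).all(axis=1) & any_called
        ok = all_hom0 | all_hom2
        pos = panel.sites["pos"].to_numpy()[idx]
        i = 0
        while i < len(ok):
            if not ok[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(ok) and ok[j + 1]:
                j += 1
            lo, hi = i, j
            outer_lo = int(pos[lo - 1]) if lo > 0 else int(pos[0])
            outer_hi = int(pos[hi + 1]) if hi < len(idx) - 1 else int(pos[-1])
            ci = CriticalInterval(
                c, int(pos[lo]), int(pos[hi]), outer_lo, outer_hi, idx[lo : hi + 1]
            )
            if anchor is None:
                key = (ci.inner_span,)
                if best_key is None or key > best_key:
                    best, best_key = ci, key
            else:
                dist = max(0, ci.inner_start - anchor, anchor - ci.inner_end)
                key = (-dist, ci.inner_span)
                if best_key is None or key > best_key:
                    best, best_key = ci, key
            i = j + 1
    if best is None:
        return CriticalInterval("", 0, 0, 0, 0, np.array([], dtype=int), found=False)
    return best


def ibd_interval_from_origins(
    hapset: HaplotypeSet, affected_ids: list[str]
) -> tuple[int, int]:
    """True IBD segment bounds shared homozygously by all affected.

    Uses the simulator's founder-origin labels: the run of sites at which
    every affected individual carries the ancestral disease label on both
    haplotypes.  Returns 1-based inclusive positions.
    """
    idx = [hapset.index_of(i) for i in affected_ids]
    both = (hapset.origins[idx] == hapset.disease_origin).all(axis=1).all(axis=0)
    on_chrom = (
        hapset.sites["chrom"] == hapset.sites["chrom"].iloc[hapset.causal_index]
    ).to_numpy()
    ok = both & on_chrom
    run = np.flatnonzero(ok)
    pos = hapset.sites["pos"].to_numpy()
    return int(pos[run[0]]), int(pos[run[-1]])
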