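"""Expression- and phenotype-level validation statistics.

Covers the validation stages that follow candidate nomination: total
transcript reduction consistent with nonsense-mediated decay (one-way
ANOVA across genotype groups), mutant-allele read depletion in
heterozygotes, a dual-contrast FDR-intersection differential-expression
criterion, cell-type marker selection and genotype-effect testing on
marker panels, and the normalized brain-weight contrast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def cpm_normalize(
    counts: pd.DataFrame, library_sizes: pd.Series | None = None
) -> pd.DataFrame:
    """Counts-per-million per sample; library sizes default to column sums."""
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any() or library_sizes.isna().any():
        bad = library_sizes.index[(library_sizes <= 0) | library_sizes.isna()]
        raise ValueError(f"non-positive library sizes for samples: {list(bad)}")
    return counts.div(library_sizes, axis=1) * 1e6


def log2_cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    return np.log2(cpm_normalize(counts, library_sizes) + 1.0)


# ---------------------------------------------------------------------------
# NMD validation
# ---------------------------------------------------------------------------

@dataclass
class ReductionResult:
    group_means: dict[str, float]
    percent_reduction: float
    anova_p: float
    posthoc: pd.DataFrame


def _anova_groups(
    values: dict[str, np.ndarray], posthoc: bool = True
) -> tuple[float, pd.DataFrame]:
    labels = list(values)
    arrays = [np.asarray(values[g], dtype=float) for g in labels]
    if np.ptp(np.concatenate(arrays)) == 0:
        p = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.f_oneway(*arrays).pvalue)
        if np.isnan(p):
            p = 1.0
    rows = []
    if posthoc:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.tukey_hsd(*arrays)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                rows.append((labels[i], labels[j], float(res.pvalue[i, j])))
    return p, pd.DataFrame(rows, columns=["group_a", "group_b", "p_adj"])


def expression_reduction_test(
    cpm: pd.DataFrame, groups: pd.Series, gene: str, posthoc: bool = True
) -> ReductionResult:
    """Percent expression reduction of ``gene`` in homozygous mutants.

    Reduction = (1 - mean(hom_mutant) / mean(hom_ref)) * 100 on the CPM
    scale, with a one-way ANOVA across genotype groups and Tukey-style
    pairwise post-hoc tests.
    """
    values = {
        g: cpm.loc[gene, groups.index[groups == g]].to_numpy(dtype=float)
        for g in pd.unique(groups)
    }
    empty = [g for g, v in values.items() if len(v) == 0]
    if empty or len(values) < 2:
        raise ValueError(f"each group needs samples; empty or missing: {empty}")
    if min(len(v) for v in values.values()) < 2:
        raise ValueError("each group needs >= 2 samples for the ANOVA")
    if "hom_mutant" not in values or "hom_ref" not in values:
        raise ValueError("groups must include hom_mutant and hom_ref")
    means = {g: float(v.mean()) for g, v in values.items()}
    reduction = (1.0 - means["hom_mutant"] / means["hom_ref"]) * 100.0
    p, pairwise = _anova_groups(values, posthoc=posthoc)
    return ReductionResult(means, reduction, p, pairwise)


@dataclass
class AlleleBiasResult:
    fractions: pd.DataFrame  # sample, gene, mutant_fraction
    gene_means: dict[str, float]
    anova_p: float
    posthoc: pd.DataFrame  # target vs each control


def _weighted_anova(values: dict[str, np.ndarray], weights: dict[str, np.ndarray]) -> float:
    """One-way ANOVA with per-observation precision weights (exact F under
    Var(y_i) = sigma^2 / w_i)."""
    y = np.concatenate([values[g] for g in values])
    w = np.concatenate([weights[g] for g in values]).astype(float)
    grp = np.concatenate([np.full(len(values[g]), i) for i, g in enumerate(values)])
    k, n = len(values), len(y)
    if n <= k or np.ptp(y) == 0:
        return 1.0
    ybar = np.average(y, weights=w)
    ssb = ssw = 0.0
    for i in range(k):
        m = grp == i
        gw = w[m].sum()
        gbar = np.average(y[m], weights=w[m])
        ssb += gw * (gbar - ybar) ** 2
        ssw += float((w[m] * (y[m] - gbar) ** 2).sum())
    if ssw <= 0:
        return 1.0
    f = (ssb / (k - 1)) / (ssw / (n - k))
    return float(stats.f.sf(f, k - 1, n - k))


def allele_bias_test(
    allele_counts: pd.DataFrame,
    target_gene: str,
    control_genes: list[str],
    posthoc: bool = True,
    weighted: bool = True,
) -> AlleleBiasResult:
    """Mutant-read fraction of the target gene vs. nearby control genes.

    The unit of comparison is the per-cat mutant-read fraction
    alt / (ref + alt); the one-way ANOVA is across genes, followed by
    Tukey post-hoc contrasts of the target against each control.  Genes
    with zero coverage in every sample are dropped with a warning.

    By default the ANOVA weights each per-cat fraction by its read depth
    (binomial sampling variance scales as 1/depth, so weighting keeps the
    F reference exact when depths span orders of magnitude);
    ``weighted=False`` gives the unweighted per-cat-fraction comparison.
    """
    df = allele_counts.copy()
    df = df[df["gene"].isin([target_gene, *control_genes])]
    df["depth"] = df["ref_reads"] + df["alt_reads"]
    usable_genes = []
    for gene in [target_gene, *control_genes]:
        sub = df[df["gene"] == gene]
        if len(sub) == 0 or (sub["depth"] <= 0).all():
            log.warning("allele_bias_test: dropping gene %s (no coverage)", gene)
            continue
        usable_genes.append(gene)
    if target_gene not in usable_genes:
        raise ValueError(f"target gene {target_gene} has no covered het samples")
    df = df[df["gene"].isin(usable_genes) & (df["depth"] > 0)].copy()
    df["mutant_fraction"] = df["alt_reads"] / df["depth"]
    values = {
        g: df.loc[df["gene"] == g, "mutant_fraction"].to_numpy() for g in usable_genes
    }
    p, posthoc_all = _anova_groups(values, posthoc=posthoc)
    if weighted:
        wts = {
            g: df.loc[df["gene"] == g, "depth"].to_numpy(dtype=float)
            for g in usable_genes
        }
        p = _weighted_anova(values, wts)
    pairwise = posthoc_all[
        (posthoc_all["group_a"] == target_gene) | (posthoc_all["group_b"] == target_gene)
    ].reset_index(drop=True)
    means = {g: float(v.mean()) for g, v in values.items()}
    return AlleleBiasResult(
        df[["sample", "gene", "mutant_fraction"]].reset_index(drop=True),
        means,
        p,
        pairwise,
    )


# ---------------------------------------------------------------------------
# Differential expression: stand-in test + BH + dual-contrast intersection
# ---------------------------------------------------------------------------

def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_de(
    cpm: pd.DataFrame,
    groups: pd.Series,
    group_a: list[str] | str,
    group_b: list[str] | str,
) -> pd.DataFrame:
    """Per-gene Welch test of log2(CPM+1) between two sample groups.

    A deliberately simple stand-in for a full count-model differential
    test; the pipeline's contribution is the contrast design and the
    strict dual-significance intersection, not the per-gene test.
    Returns gene, log2fc (a minus b), p, q.
    """
    ga = [group_a] if isinstance(group_a, str) else list(group_a)
    gb = [group_b] if isinstance(group_b, str) else list(group_b)
    sa = groups.index[groups.isin(ga)]
    sb = groups.index[groups.isin(gb)]
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each side of the contrast needs >= 2 samples")
    a = np.log2(cpm[sa].to_numpy(dtype=float) + 1.0)
    b = np.log2(cpm[sb].to_numpy(dtype=float) + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    out = pd.DataFrame(
        {
            "gene": cpm.index,
            "log2fc": a.mean(axis=1) - b.mean(axis=1),
            "p": p,
            "q": bh_adjust(p),
        }
    )
    return out


def _nb_fit(
    y: np.ndarray, s: np.ndarray, alpha: float, n_iter: int = 40
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene NB mean-rate MLE with known dispersion and offsets.

    ``y`` is (genes, samples), ``s`` the library-size offsets.  Returns the
    fitted rate per gene and the maximized log-likelihood (constant terms
    in y and alpha omitted; they cancel in likelihood ratios).
    """
    mu = np.clip(y.sum(axis=1) / s.sum(), 1e-8, None)
    beta = np.log(mu)
    for _ in range(n_iter):
        t = np.exp(beta)[:, None] * s[None, :]
        grad = ((y - t) / (1 + alpha * t)).sum(axis=1)
        hess = (-t * (1 + alpha * y) / (1 + alpha * t) ** 2).sum(axis=1)
        step = np.where(hess < 0, grad / -hess, 0.0)
        beta = beta + np.clip(step, -4, 4)
    t = np.exp(beta)[:, None] * s[None, :]
    if alpha > 0:
        ll = (y * np.log(t + 1e-300) - (y + 1.0 / alpha) * np.log1p(alpha * t)).sum(axis=1)
    else:
        ll = (y * np.log(t + 1e-300) - t).sum(axis=1)
    return np.exp(beta), ll


def estimate_dispersion(counts: pd.DataFrame, groups: pd.Series) -> float:
    """Shared NB dispersion by Cox-Reid adjusted profile likelihood.

    Maximizes the summed per-gene adjusted profile log-likelihood over a
    log-spaced dispersion grid, with group means re-fitted at each
    candidate (common-dispersion estimation in the edgeR style; the CR
    term corrects the downward bias from estimating the group means).
    """
    from scipy.special import gammaln

    lib = counts.sum(axis=0).to_numpy(dtype=float)
    y = counts.to_numpy(dtype=float)
    keep = y.sum(axis=1) > 0
    y = y[keep]
    if y.size == 0:
        return 0.0
    lbl = groups.reindex(counts.columns).to_numpy()
    group_cols = [np.flatnonzero(lbl == g) for g in pd.unique(lbl)]
    group_cols = [c for c in group_cols if len(c) >= 2]

    def apl(alpha: float) -> float:
        total = 0.0
        for cols in group_cols:
            yc, sc = y[:, cols], lib[cols]
            mu, _ = _nb_fit(yc, sc, alpha)
            t = mu[:, None] * sc[None, :]
            r = 1.0 / alpha
            ll = (
                gammaln(yc + r) - gammaln(r) - gammaln(yc + 1.0)
                + yc * np.log(alpha * t / (1 + alpha * t) + 1e-300)
                - r * np.log1p(alpha * t)
            ).sum(axis=1)
            info = (t * (1 + alpha * yc) / (1 + alpha * t) ** 2).sum(axis=1)
            total += float((ll - 0.5 * np.log(info + 1e-300)).sum())
        return total

    grid = np.concatenate([[1e-6], np.logspace(-4, 1, 30)])
    scores = [apl(a) for a in grid]
    i = int(np.argmax(scores))
    if i == 0:
        return 0.0
    # golden-section refinement around the best grid point
    from scipy.optimize import minimize_scalar

    lo = np.log(grid[max(1, i - 1)])
    hi = np.log(grid[min(len(grid) - 1, i + 1)])
    res = minimize_scalar(
        lambda la: -apl(np.exp(la)), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


def nb_lrt_de(
    counts: pd.DataFrame,
    groups: pd.Series,
    group_a: list[str] | str,
    group_b: list[str] | str,
    library_sizes: pd.Series | None = None,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-gene negative-binomial likelihood-ratio contrast on raw counts.

    Shared dispersion (method-of-moments across genes unless given), log
    library-size offsets, and a 1-df chi-square likelihood ratio per gene
    for the two-group mean contrast.  Substantially better powered than
    the Welch stand-in at the pipeline's small group sizes.  Returns gene,
    log2fc (a over b), p, q.
    """
    ga = [group_a] if isinstance(group_a, str) else list(group_a)
    gb = [group_b] if isinstance(group_b, str) else list(group_b)
    sa = [c for c in counts.columns if groups.get(c) in ga]
    sb = [c for c in counts.columns if groups.get(c) in gb]
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each side of the contrast needs >= 2 samples")
    sub = counts[sa + sb]
    lib = (
        sub.sum(axis=0) if library_sizes is None else library_sizes.reindex(sub.columns)
    ).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("non-positive library sizes")
    if dispersion is None:
        lbl = pd.Series(["a"] * len(sa) + ["b"] * len(sb), index=sa + sb)
        dispersion = estimate_dispersion(sub, lbl)
    y = sub.to_numpy(dtype=float)
    na = len(sa)
    mu_a, ll_a = _nb_fit(y[:, :na], lib[:na], dispersion)
    mu_b, ll_b = _nb_fit(y[:, na:], lib[na:], dispersion)
    _, ll_0 = _nb_fit(y, lib, dispersion)
    lrt = np.clip(2.0 * (ll_a + ll_b - ll_0), 0.0, None)
    p = stats.chi2.sf(lrt, df=1)
    nonzero = y.sum(axis=1) > 0
    p = np.where(nonzero, p, 1.0)
    log2fc = np.log2((mu_a + 1e-12) / (mu_b + 1e-12))
    return pd.DataFrame(
        {"gene": counts.index, "log2fc": log2fc, "p": p, "q": bh_adjust(p)}
    )


def de_intersection(
    result_a: pd.DataFrame,
    result_b: pd.DataFrame,
    q_threshold: float = 0.05,
) -> dict[str, list[str]]:
    """Genes significant (q < threshold) in both contrasts.

    Requires identical gene universes; genes significant in both but with
    discordant effect signs are reported separately rather than counted.
    """
    ua, ub = set(result_a["gene"]), set(result_b["gene"])
    if ua != ub:
        diff = sorted((ua - ub) | (ub - ua))
        raise ValueError(f"gene universes differ: {diff[:10]}")
    a = result_a.set_index("gene")
    b = result_b.set_index("gene")
    sig = (a["q"] < q_threshold) & (b["q"] < q_threshold)
    same_sign = np.sign(a["log2fc"]) == np.sign(b["log2fc"])
    concordant = sorted(a.index[sig & same_sign])
    discordant = sorted(a.index[sig & ~same_sign])
    return {"concordant": concordant, "discordant": discordant}


# ---------------------------------------------------------------------------
# Cell-type composition
# ---------------------------------------------------------------------------

def select_celltype_markers(
    reference: pd.DataFrame,
    fold: float = 2.0,
    p_max: float = 0.2,
) -> dict[str, list[str]]:
    """Marker genes per cell type from a replicated reference table.

    A gene marks cell type t when its mean abundance in t is at least
    ``fold`` times the mean in every other type (boundary inclusive) and a
    Welch two-sample test against the runner-up type has raw p < ``p_max``
    (strict).  Cell types with fewer than 2 replicates are excluded.
    """
    counts = reference.groupby("cell_type")["replicate"].nunique()
    usable = counts.index[counts >= 2].tolist()
    dropped = counts.index[counts < 2].tolist()
    if dropped:
        log.warning("select_celltype_markers: excluding %s (<2 replicates)", dropped)
    ref = reference[reference["cell_type"].isin(usable)]
    markers: dict[str, list[str]] = {t: [] for t in usable}
    for gene, sub in ref.groupby("gene"):
        means = sub.groupby("cell_type")["abundance"].mean()
        if len(means) < 2:
            continue
        top = means.idxmax()
        runner = means.drop(top).idxmax()
        if means[top] < fold * means[runner]:
            continue
        a = sub.loc[sub["cell_type"] == top, "abundance"].to_numpy()
        b = sub.loc[sub["cell_type"] == runner, "abundance"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        if np.isnan(p):
            continue
        if p < p_max:
            markers[top].append(gene)
    return {t: sorted(g) for t, g in markers.items()}


def _genotype_permutation_p(
    x: np.ndarray, labels: np.ndarray, max_perms: int = 5000
) -> float:
    """Permutation p for the genotype main effect in the additive two-way fit.

    ``x`` is (genes, samples) log expression.  With every gene measured in
    every sample the gene factor is orthogonal to any sample partition, so
    the genotype F is a monotone function of the between-group sum of
    squares of per-sample means — permuting sample labels only needs those
    means.  Samples are exchangeable under the null, so the permutation
    reference is exactly calibrated regardless of per-gene variance
    heterogeneity.
    """
    from math import comb

    s_mean = x.mean(axis=0)  # per-sample mean over genes
    n = len(s_mean)
    uniq, counts = np.unique(labels, return_counts=True)

    def ss_between_many(label_mat: np.ndarray) -> np.ndarray:
        tot = s_mean.mean()
        ss = np.zeros(label_mat.shape[0])
        for gi, g in enumerate(uniq):
            m = label_mat == gi
            ss += counts[gi] * (m @ s_mean / counts[gi] - tot) ** 2
        return ss

    codes = np.array([int(np.where(uniq == l)[0][0]) for l in labels])
    n_distinct = 1
    rem = n
    for c in counts:
        n_distinct *= comb(rem, int(c))
        rem -= int(c)
    if n_distinct <= max_perms:
        mats = np.array([m for m in _all_label_orders(codes)])
        exhaustive = True
    else:
        rng = np.random.default_rng(0)
        mats = np.array([rng.permutation(codes) for _ in range(max_perms - 1)])
        exhaustive = False
    obs = float(ss_between_many(codes[None, :])[0])
    hits = int((ss_between_many(mats) >= obs - 1e-12).sum())
    return hits / len(mats) if exhaustive else (1 + hits) / (1 + len(mats))


def _all_label_orders(labels: np.ndarray) -> list[np.ndarray]:
    """All distinct arrangements of a multiset of labels."""
    import itertools

    n = len(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    out: list[np.ndarray] = []

    # choose index sets per label iteratively
    def build(idx_pool: tuple[int, ...], li: int, current: np.ndarray):
        if li == len(uniq):
            out.append(current.copy())
            return
        lab, c = uniq[li], counts[li]
        for combo in itertools.combinations(idx_pool, int(c)):
            nxt = current.copy()
            for j in combo:
                nxt[j] = lab
            rest = tuple(j for j in idx_pool if j not in combo)
            build(rest, li + 1, nxt)

    build(tuple(range(n)), 0, np.empty(n, dtype=labels.dtype))
    return out


def celltype_shift_test(
    cpm: pd.DataFrame,
    markers: dict[str, list[str]],
    groups: pd.Series,
    p_method: str = "permutation",
) -> pd.DataFrame:
    """Genotype effect on cell-type marker panels (two-way ANOVA).

    For each cell type with >= 2 marker genes present in the matrix, fits
    log2(CPM+1) ~ genotype group + gene and reports the genotype
    main-effect F-test plus the direction of the hom_mutant shift
    relative to hom_ref.  By default the genotype p comes from the exact
    permutation reference of the same statistic (sample labels are
    exchangeable under the null; the parametric F is miscalibrated when
    per-gene variances differ); ``p_method='parametric'`` reports the
    classical F p-value.
    """
    if p_method not in ("permutation", "parametric"):
        raise ValueError(f"unknown p_method {p_method!r}")
    rows = []
    for cell_type, genes in markers.items():
        present = [g for g in genes if g in cpm.index]
        if len(present) < 2:
            log.warning("celltype_shift_test: skipping %s (<2 marker genes)", cell_type)
            continue
        x = np.log2(cpm.loc[present].to_numpy(dtype=float) + 1.0)
        labels = groups.reindex(cpm.columns).to_numpy()
        if p_method == "permutation":
            p = _genotype_permutation_p(x, labels)
        else:
            long = (
                np.log2(cpm.loc[present] + 1.0)
                .reset_index(names="gene")
                .melt(id_vars="gene", var_name="sample", value_name="expr")
            )
            long["group"] = groups.reindex(long["sample"]).to_numpy()
            model = ols("expr ~ C(group) + C(gene)", data=long).fit()
            table = anova_lm(model, typ=2)
            p = float(table.loc["C(group)", "PR(>F)"])
        mut = x[:, labels == "hom_mutant"].mean()
        ref = x[:, labels == "hom_ref"].mean()
        rows.append(
            {
                "cell_type": cell_type,
                "n_markers": len(present),
                "p_genotype": p,
                "direction": "increased" if mut > ref else "decreased",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Brain-weight contrast
# ---------------------------------------------------------------------------

@dataclass
class BrainWeightResult:
    group_means: dict[str, float]  # g per kg
    percent_decrease: float
    percent_decrease_rounded: int


def brain_weight_contrast(
    brain_g: np.ndarray,
    body_kg: np.ndarray,
    labels: list[str] | np.ndarray,
) -> BrainWeightResult:
    """Normalized brain weight (g/kg) of affected vs. all other animals.

    Percent decrease = (1 - mean_affected / mean_control) * 100, control
    pooling unaffected and carrier animals, rounded to the nearest
    integer percent.
    """
    brain = np.asarray(brain_g, dtype=float)
    body = np.asarray(body_kg, dtype=float)
    labels = np.asarray(labels)
    if (brain <= 0).any() or (body <= 0).any():
        raise ValueError("brain and body weights must be positive")
    norm = brain / body
    affected = labels == "affected"
    if not affected.any() or affected.all():
        raise ValueError("need both affected and control animals")
    means = {
        lbl: float(norm[labels == lbl].mean()) for lbl in np.unique(labels)
    }
    mean_aff = float(norm[affected].mean())
    mean_ctrl = float(norm[~affected].mean())
    pct = (1.0 - mean_aff / mean_ctrl) * 100.0
    return BrainWeightResult(means, pct, int(round(pct)))
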