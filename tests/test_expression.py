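"""Expression simulator identities and the validation statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import colonymap as cm
from colonymap.expression import nb_lrt_de

from conftest import default_dosages, het_group_series


# ---------------------------------------------------------------------------
# Simulator identities (NMD model)
# ---------------------------------------------------------------------------

def test_nmd_identities_at_default_retention():
    cfg = cm.ExpressionSimConfig(nmd_retention=0.41)
    assert cfg.homozygote_reduction == pytest.approx(0.59)
    assert cfg.het_mutant_fraction == pytest.approx(0.2908, abs=1e-4)


def test_nmd_null_model_lambda_one():
    cfg = cm.ExpressionSimConfig(nmd_retention=1.0)
    assert cfg.homozygote_reduction == pytest.approx(0.0)
    assert cfg.het_mutant_fraction == pytest.approx(0.5)


def test_nmd_complete_decay_lambda_zero():
    cfg = cm.ExpressionSimConfig(nmd_retention=0.0, n_genes=50)
    b = cm.simulate_expression(None, default_dosages(), cfg, seed=1)
    hom = b.groups.index[b.groups == "hom_mutant"]
    assert (b.counts.loc[b.target_gene, hom] == 0).all()
    target_ac = b.allele_counts[b.allele_counts["gene"] == b.target_gene]
    assert (target_ac["alt_reads"] == 0).all()


def test_invalid_retention_rejected():
    with pytest.raises(cm.ConfigError):
        cm.ExpressionSimConfig(nmd_retention=1.5)


def test_expression_sim_deterministic():
    cfg = cm.ExpressionSimConfig(n_genes=100)
    a = cm.simulate_expression(None, default_dosages(), cfg, seed=3)
    b = cm.simulate_expression(None, default_dosages(), cfg, seed=3)
    assert a.counts.equals(b.counts)
    assert a.allele_counts.equals(b.allele_counts)


def test_het_mutant_read_fraction_converges_to_pi():
    """Pooled mutant-read fraction over many het measurements approaches
    pi = lambda / (1 + lambda) within 3 binomial standard errors."""
    cfg = cm.ExpressionSimConfig(n_genes=20)
    alt = tot = 0
    for seed in range(60):
        b = cm.simulate_expression(None, default_dosages(), cfg, seed=seed)
        t = b.allele_counts[b.allele_counts["gene"] == b.target_gene]
        alt += t["alt_reads"].sum()
        tot += (t["alt_reads"] + t["ref_reads"]).sum()
    pi = cfg.het_mutant_fraction
    se = np.sqrt(pi * (1 - pi) / tot)
    assert abs(alt / tot - pi) < 3 * se


# ---------------------------------------------------------------------------
# CPM
# ---------------------------------------------------------------------------

def test_cpm_basic_and_conservation():
    counts = pd.DataFrame({"s1": [10, 0], "s2": [5, 5]}, index=["g1", "g2"])
    lib = pd.Series({"s1": 1e6, "s2": 1e6})
    cpm = cm.cpm_normalize(counts, lib)
    assert cpm.loc["g1", "s1"] == pytest.approx(10.0)
    own = cm.cpm_normalize(counts)
    assert own.sum(axis=0).to_numpy() == pytest.approx([1e6, 1e6])


def test_cpm_zero_library_rejected():
    counts = pd.DataFrame({"s1": [0]}, index=["g"])
    with pytest.raises(ValueError):
        cm.cpm_normalize(counts)


# ---------------------------------------------------------------------------
# Reduction test
# ---------------------------------------------------------------------------

def test_reduction_null_identical_means():
    groups = het_group_series()
    rng = np.random.default_rng(0)
    base = rng.normal(100, 1, size=10)
    cpm = pd.DataFrame([base], index=["G"], columns=groups.index)
    # same distribution in all groups: reduction near 0, p not small
    res = cm.expression_reduction_test(cpm, groups, "G")
    assert abs(res.percent_reduction) < 5
    assert res.anova_p > 0.05
    flat = pd.DataFrame([[100.0] * 10], index=["G"], columns=groups.index)
    res2 = cm.expression_reduction_test(flat, groups, "G")
    assert res2.percent_reduction == pytest.approx(0.0)
    assert res2.anova_p == pytest.approx(1.0)


def test_reduction_scale_invariance():
    groups = het_group_series()
    rng = np.random.default_rng(1)
    cpm = pd.DataFrame([rng.uniform(50, 150, 10)], index=["G"], columns=groups.index)
    r1 = cm.expression_reduction_test(cpm, groups, "G").percent_reduction
    r2 = cm.expression_reduction_test(2 * cpm, groups, "G").percent_reduction
    assert r1 == pytest.approx(r2)


def test_reduction_requires_groups():
    groups = het_group_series()[:6]  # drops hom_ref
    cpm = pd.DataFrame([np.arange(6.0)], index=["G"], columns=groups.index)
    with pytest.raises(ValueError):
        cm.expression_reduction_test(cpm, groups, "G")


def test_reduction_recovers_59_percent():
    """lambda = 0.41 colonies: mean estimated reduction within 5 points of 59."""
    cfg = cm.ExpressionSimConfig(n_genes=200)
    reds = []
    for seed in range(50):
        b = cm.simulate_expression(None, default_dosages(), cfg, seed=seed)
        cpm = cm.cpm_normalize(b.counts, b.library_sizes)
        res = cm.expression_reduction_test(cpm, b.groups, b.target_gene, posthoc=False)
        reds.append(res.percent_reduction)
    assert abs(np.mean(reds) - 59.0) < 5.0


# ---------------------------------------------------------------------------
# Allele bias
# ---------------------------------------------------------------------------

def _bias_table(rng, pi_target, n_samples=3):
    rows = []
    for s in range(n_samples):
        for g in ["T", "C1", "C2", "C3"]:
            depth = int(np.exp(rng.uniform(np.log(24), np.log(3000))))
            frac = pi_target if g == "T" else 0.5
            alt = rng.binomial(depth, frac)
            rows.append((f"H{s}", g, depth - alt, alt))
    return pd.DataFrame(rows, columns=["sample", "gene", "ref_reads", "alt_reads"])


def test_allele_bias_balanced_reads_not_significant():
    rows = [(f"H{s}", g, 50, 50) for s in range(3) for g in ["T", "C1", "C2"]]
    ac = pd.DataFrame(rows, columns=["sample", "gene", "ref_reads", "alt_reads"])
    res = cm.allele_bias_test(ac, "T", ["C1", "C2"])
    assert all(v == pytest.approx(0.5) for v in res.gene_means.values())
    assert res.anova_p > 0.9


def test_allele_bias_label_swap_symmetry():
    rng = np.random.default_rng(2)
    ac = _bias_table(rng, 0.3)
    res = cm.allele_bias_test(ac, "T", ["C1", "C2", "C3"])
    swapped = ac.rename(columns={"ref_reads": "alt_reads", "alt_reads": "ref_reads"})
    res2 = cm.allele_bias_test(swapped, "T", ["C1", "C2", "C3"])
    for g in res.gene_means:
        assert res2.gene_means[g] == pytest.approx(1 - res.gene_means[g])


def test_allele_bias_drops_uncovered_gene():
    rows = [("H0", "T", 30, 10), ("H1", "T", 40, 12), ("H0", "C1", 50, 48),
            ("H1", "C1", 60, 55), ("H0", "C2", 0, 0), ("H1", "C2", 0, 0)]
    ac = pd.DataFrame(rows, columns=["sample", "gene", "ref_reads", "alt_reads"])
    res = cm.allele_bias_test(ac, "T", ["C1", "C2"])
    assert "C2" not in res.gene_means


def test_allele_bias_recovers_pi_and_significance():
    """Target at pi ~ 0.29, controls at 0.5, study read depths: the estimated
    target fraction tracks pi and the ANOVA is strongly significant."""
    rng = np.random.default_rng(3)
    fracs, sig = [], 0
    for _ in range(50):
        ac = _bias_table(rng, 0.2908)
        res = cm.allele_bias_test(ac, "T", ["C1", "C2", "C3"], posthoc=False)
        fracs.append(res.gene_means["T"])
        sig += res.anova_p < 0.001
    assert abs(np.mean(fracs) - 0.2908) < 0.03
    assert sig >= 45  # >= 90% of seeds


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def test_bh_single_p():
    assert cm.bh_adjust([0.03]) == pytest.approx([0.03])


def test_bh_hand_computed_example():
    """q_i = min over j>=i of p_j * m / j: all collapse to 0.04 here."""
    q = cm.bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        cm.bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        cm.bh_adjust([-0.1])


@settings(deadline=None, max_examples=50)
@given(
    st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=30)
)
def test_bh_order_invariance_and_monotonicity(ps):
    ps = np.asarray(ps)
    q = cm.bh_adjust(ps)
    assert (q >= ps - 1e-12).all()
    perm = np.random.default_rng(0).permutation(len(ps))
    q_perm = cm.bh_adjust(ps[perm])
    assert np.allclose(np.sort(q), np.sort(q_perm))
    order = np.argsort(ps, kind="mergesort")
    assert (np.diff(q[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# DE contrasts and intersection
# ---------------------------------------------------------------------------

def test_de_intersection_set_logic():
    def mk(genes, sig, signs):
        return pd.DataFrame(
            {
                "gene": genes,
                "log2fc": signs,
                "p": [0.001 if s else 0.5 for s in sig],
                "q": [0.01 if s else 0.9 for s in sig],
            }
        )

    genes = ["g1", "g2", "g3", "g4"]
    a = mk(genes, [True, True, True, False], [1, 1, -1, 1])
    b = mk(genes, [False, True, True, True], [1, 1, 1, 1])
    out = cm.de_intersection(a, b)
    assert out["concordant"] == ["g2"]
    assert out["discordant"] == ["g3"]


def test_de_intersection_disjoint_and_universe_mismatch():
    a = pd.DataFrame({"gene": ["g1"], "log2fc": [1.0], "p": [0.001], "q": [0.01]})
    b = pd.DataFrame({"gene": ["g1"], "log2fc": [1.0], "p": [0.9], "q": [0.9]})
    assert cm.de_intersection(a, b)["concordant"] == []
    c = pd.DataFrame({"gene": ["g2"], "log2fc": [1.0], "p": [0.9], "q": [0.9]})
    with pytest.raises(ValueError):
        cm.de_intersection(a, c)


def test_planted_de_genes_recovered_by_dual_contrast():
    """20 planted concordant DE genes, hom_mutant (4) vs unaffected (6) and
    vs hom_ref (3): NB-LRT intersection recovers them with high sensitivity
    and few false positives."""
    no_shift = {
        t: (n, 1.0) for t, (n, _s) in cm.ExpressionSimConfig().cell_types.items()
    }
    sens, fps = [], []
    for seed in range(10):
        cfg = cm.ExpressionSimConfig(
            n_de_genes=20, de_log2fc=2.0, n_genes=1000, cell_types=no_shift
        )
        b = cm.simulate_expression(None, default_dosages(), cfg, seed=seed)
        counts = b.counts.drop(index=[b.target_gene])  # the target is truly DE
        de_a = nb_lrt_de(counts, b.groups, "hom_mutant", ["het", "hom_ref"])
        de_b = nb_lrt_de(counts, b.groups, "hom_mutant", "hom_ref")
        inter = cm.de_intersection(de_a, de_b)
        hits = [g for g in inter["concordant"] if g.startswith("DE_")]
        fps.append(len(inter["concordant"]) - len(hits))
        sens.append(len(hits) / 20)
    assert np.mean(sens) >= 0.8
    assert np.mean(fps) <= 2.0


def test_welch_de_effect_sign_and_significance_on_constructed_input():
    groups = het_group_series()
    rng = np.random.default_rng(8)
    n_genes = 50
    base = 2 ** rng.normal(8, 1, size=(n_genes, 10))
    cpm = pd.DataFrame(base, index=[f"g{i}" for i in range(n_genes)],
                       columns=groups.index)
    # plant an 8-fold drop in hom_mutant for gene g0 with tight noise
    mut = groups.index[groups == "hom_mutant"]
    cpm.loc["g0"] = 256.0 * 2 ** rng.normal(0, 0.1, size=10)
    cpm.loc["g0", mut] /= 8.0
    de = cm.welch_de(cpm, groups, "hom_mutant", "hom_ref").set_index("gene")
    assert de.loc["g0", "log2fc"] == pytest.approx(-3.0, abs=0.5)
    assert de.loc["g0", "p"] < 0.01
    # constant gene is assigned p = 1, not NaN
    cpm.loc["g1"] = 100.0
    de2 = cm.welch_de(cpm, groups, "hom_mutant", "hom_ref").set_index("gene")
    assert de2.loc["g1", "p"] == 1.0


# ---------------------------------------------------------------------------
# Cell-type markers and shift test
# ---------------------------------------------------------------------------

def reference_from(rows):
    return pd.DataFrame(rows, columns=["gene", "cell_type", "replicate", "abundance"])


def test_flat_gene_is_not_a_marker():
    rows = [
        ("g", t, r, 10.0 + 0.01 * r) for t in ["ast", "oli"] for r in range(3)
    ]
    markers = cm.select_celltype_markers(reference_from(rows))
    assert all(g == [] for g in markers.values())


def test_clear_marker_selected():
    rows = [("g", "ast", r, 30.0 + 0.1 * r) for r in range(3)]
    rows += [("g", t, r, 10.0 + 0.1 * r) for t in ["oli", "neu"] for r in range(3)]
    markers = cm.select_celltype_markers(reference_from(rows))
    assert markers["ast"] == ["g"]


def test_exact_twofold_boundary_included():
    rows = [("g", "ast", r, v) for r, v in enumerate([19.8, 20.0, 20.2])]
    rows += [("g", "oli", r, v) for r, v in enumerate([9.9, 10.0, 10.1])]
    ref = reference_from(rows)
    assert cm.select_celltype_markers(ref, fold=2.0)["ast"] == ["g"]
    # nudge the candidate below 2.0-fold: excluded
    ref2 = ref.copy()
    ref2.loc[ref2["cell_type"] == "ast", "abundance"] -= 0.2
    assert cm.select_celltype_markers(ref2, fold=2.0)["ast"] == []


def test_marker_rule_matches_brute_force_oracle():
    from scipy import stats as sps

    rng = np.random.default_rng(6)
    rows = []
    genes = [f"g{i}" for i in range(30)]
    types = ["ast", "oli", "opc"]
    for g in genes:
        for t in types:
            base = rng.uniform(5, 40)
            for r in range(3):
                rows.append((g, t, r, base * rng.lognormal(0, 0.2)))
    ref = reference_from(rows)
    got = cm.select_celltype_markers(ref)
    for g in genes:
        sub = ref[ref["gene"] == g]
        means = sub.groupby("cell_type")["abundance"].mean()
        top = means.idxmax()
        runner = means.drop(top).idxmax()
        expected = False
        if means[top] >= 2.0 * means[runner]:
            a = sub.loc[sub["cell_type"] == top, "abundance"]
            b = sub.loc[sub["cell_type"] == runner, "abundance"]
            p = sps.ttest_ind(a, b, equal_var=False).pvalue
            expected = p < 0.2
        assert (g in got[top]) == expected


def test_reference_type_with_single_replicate_excluded():
    rows = [("g", "ast", 0, 100.0)] + [("g", "oli", r, 10.0 + r) for r in range(3)]
    markers = cm.select_celltype_markers(reference_from(rows))
    assert "ast" not in markers


def test_celltype_shift_detected_with_direction():
    dos = default_dosages()
    cfg = cm.ExpressionSimConfig(
        n_genes=500, cell_types={"astrocyte": (20, 1.5), "neuron": (20, 1.0)}
    )
    detected = 0
    for seed in range(10):
        b = cm.simulate_expression(None, dos, cfg, seed=seed)
        cpm = cm.cpm_normalize(b.counts, b.library_sizes)
        res = cm.celltype_shift_test(cpm, b.marker_genes, b.groups).set_index("cell_type")
        if (
            res.loc["astrocyte", "p_genotype"] < 0.01
            and res.loc["astrocyte", "direction"] == "increased"
        ):
            detected += 1
        assert res.loc["neuron", "p_genotype"] > 0.001 or seed > 0  # no planted effect
    assert detected >= 9


def test_label_permutation_destroys_celltype_shift():
    dos = default_dosages()
    cfg = cm.ExpressionSimConfig(n_genes=300, cell_types={"astrocyte": (20, 1.6)})
    b = cm.simulate_expression(None, dos, cfg, seed=0)
    cpm = cm.cpm_normalize(b.counts, b.library_sizes)
    true_p = float(
        cm.celltype_shift_test(cpm, b.marker_genes, b.groups)["p_genotype"].iloc[0]
    )
    rng = np.random.default_rng(0)
    perm_ps = []
    for _ in range(20):
        perm = pd.Series(
            rng.permutation(b.groups.to_numpy()), index=b.groups.index
        )
        perm_ps.append(
            float(cm.celltype_shift_test(cpm, b.marker_genes, perm)["p_genotype"].iloc[0])
        )
    assert true_p < 0.01
    assert np.median(perm_ps) > 0.05


def test_too_few_markers_skipped():
    groups = het_group_series()
    cpm = pd.DataFrame(
        np.random.default_rng(0).uniform(1, 10, size=(1, 10)),
        index=["only"], columns=groups.index,
    )
    res = cm.celltype_shift_test(cpm, {"ast": ["only"]}, groups)
    assert res.empty


def test_statistics_invariant_to_gene_and_sample_ordering():
    cfg = cm.ExpressionSimConfig(n_genes=100)
    b = cm.simulate_expression(None, default_dosages(), cfg, seed=4)
    cpm = cm.cpm_normalize(b.counts, b.library_sizes)
    rng = np.random.default_rng(0)
    cpm_shuf = cpm.iloc[rng.permutation(len(cpm)), rng.permutation(cpm.shape[1])]
    r1 = cm.expression_reduction_test(cpm, b.groups, b.target_gene, posthoc=False)
    r2 = cm.expression_reduction_test(cpm_shuf, b.groups, b.target_gene, posthoc=False)
    assert r1.percent_reduction == pytest.approx(r2.percent_reduction)
    assert r1.anova_p == pytest.approx(r2.anova_p)
    d1 = cm.welch_de(cpm, b.groups, "hom_mutant", "hom_ref").set_index("gene")
    d2 = cm.welch_de(cpm_shuf, b.groups, "hom_mutant", "hom_ref").set_index("gene")
    assert np.allclose(d1.loc[d2.index, "p"], d2["p"])


# ---------------------------------------------------------------------------
# Brain weight
# ---------------------------------------------------------------------------

def test_brain_weight_printed_group_means():
    """Group means of 4.3 and 7.8 g/kg give a 45% decrease (44.87 rounded)."""
    brain = np.array([4.3 * 3.0, 4.3 * 3.4, 7.8 * 3.1, 7.8 * 3.3])
    body = np.array([3.0, 3.4, 3.1, 3.3])
    labels = ["affected", "affected", "unaffected", "carrier"]
    res = cm.brain_weight_contrast(brain, body, labels)
    assert res.percent_decrease == pytest.approx(44.87, abs=0.01)
    assert res.percent_decrease_rounded == 45


def test_brain_weight_identical_groups_zero():
    res = cm.brain_weight_contrast(
        [7.0, 7.0, 7.0], [1.0, 1.0, 1.0], ["affected", "unaffected", "carrier"]
    )
    assert res.percent_decrease == pytest.approx(0.0)


def test_brain_weight_body_scale_invariance():
    brain = np.array([10.0, 12.0, 20.0, 22.0])
    body = np.array([2.0, 2.5, 2.2, 2.4])
    labels = ["affected", "affected", "unaffected", "unaffected"]
    a = cm.brain_weight_contrast(brain, body, labels)
    b = cm.brain_weight_contrast(brain, body * 3.0, labels)
    assert a.percent_decrease == pytest.approx(b.percent_decrease)


def test_brain_weight_rejects_bad_input():
    with pytest.raises(ValueError):
        cm.brain_weight_contrast([1.0, -1.0], [1.0, 1.0], ["affected", "unaffected"])
    with pytest.raises(ValueError):
        cm.brain_weight_contrast([1.0, 2.0], [1.0, 1.0], ["affected", "affected"])
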