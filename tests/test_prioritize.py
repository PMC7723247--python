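"""Coding-effect annotation, codon arithmetic, ranking, HWE extrapolation."""

import numpy as np
import pandas as pd
import pytest

import colonymap as cm
from colonymap.prioritize import (
    _CODON_TABLE,
    AnnotationError,
    TranscriptModel,
    annotate_coding_effect,
    filter_and_rank,
    hgvs_codon_index,
    hwe_extrapolate,
)


# ---------------------------------------------------------------------------
# Codon arithmetic
# ---------------------------------------------------------------------------

def test_codon_index_of_coding_deletion():
    """The single-base deletion at coding position 176 disrupts codon 59."""
    assert hgvs_codon_index(176) == 59


@pytest.mark.parametrize("pos,codon", [(1, 1), (3, 1), (4, 2)])
def test_codon_boundaries(pos, codon):
    assert hgvs_codon_index(pos) == codon


def test_codon_index_matches_triplet_enumeration():
    """Exhaustive oracle: build codons triplet by triplet over 1..300."""
    oracle = {}
    codon = 0
    for pos in range(1, 301):
        if (pos - 1) % 3 == 0:
            codon += 1
        oracle[pos] = codon
    for pos in range(1, 301):
        assert hgvs_codon_index(pos) == oracle[pos]


def test_codon_index_rejects_nonpositive():
    with pytest.raises(ValueError):
        hgvs_codon_index(0)


# ---------------------------------------------------------------------------
# Coding effect annotation
# ---------------------------------------------------------------------------

def toy_transcript(strand="+"):
    """60-codon CDS split over 2 exons on chr1."""
    rng = np.random.default_rng(9)
    body = "".join(rng.choice(list("ACGT"), size=174))
    seq = "ATG" + body + "TAA"
    assert len(seq) == 180
    if strand == "+":
        exons = [(101, 190), (301, 390)]
    else:
        exons = [(101, 190), (301, 390)]
    return TranscriptModel("TOY", "chr1", strand, exons, seq)


def _genomic_base(tm, gpos):
    cpos = tm.cds_position(gpos)
    base = tm.cds_sequence[cpos - 1]
    if tm.strand == "-":
        base = {"A": "T", "C": "G", "G": "C", "T": "A"}[base]
    return base


def _oracle_consequence(tm, gpos, alt):
    """Independent codon-by-codon translation of the full mutant CDS."""
    cpos = tm.cds_position(gpos)
    seq = list(tm.cds_sequence)
    a = alt if tm.strand == "+" else {"A": "T", "C": "G", "G": "C", "T": "A"}[alt]
    seq[cpos - 1] = a
    mutant = "".join(seq)
    ref_prot = [_CODON_TABLE[tm.cds_sequence[i : i + 3]] for i in range(0, 180, 3)]
    alt_prot = [_CODON_TABLE[mutant[i : i + 3]] for i in range(0, 180, 3)]
    if ref_prot == alt_prot:
        return "synonymous"
    i = next(i for i in range(60) if ref_prot[i] != alt_prot[i])
    if alt_prot[i] == "*" or ref_prot[i] == "*":
        return "other_lof"
    return "missense"


@pytest.mark.parametrize("strand", ["+", "-"])
def test_snv_consequences_match_translation_oracle(strand):
    tm = toy_transcript(strand)
    rng = np.random.default_rng(4)
    checked = 0
    for exon in tm.cds_exons:
        for gpos in range(exon[0], exon[1] + 1, 7):
            ref = _genomic_base(tm, gpos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                got = annotate_coding_effect(("chr1", gpos, ref, alt), tm)
                assert got == _oracle_consequence(tm, gpos, alt)
                checked += 1
    assert checked > 50


def test_indel_frame_rules():
    tm = toy_transcript()
    assert annotate_coding_effect(("chr1", 150, "NX", "N"), tm) == "frameshift"
    assert annotate_coding_effect(("chr1", 150, "NXYZ", "N"), tm) == "inframe"
    assert annotate_coding_effect(("chr1", 150, "N", "NX"), tm) == "frameshift"
    assert annotate_coding_effect(("chr1", 10, "NX", "N"), tm) == "noncoding"


def test_noncoding_and_wrong_chrom():
    tm = toy_transcript()
    assert annotate_coding_effect(("chr1", 50, "A", "G"), tm) == "noncoding"
    assert annotate_coding_effect(("chr9", 150, "A", "G"), tm) == "noncoding"


def test_reference_mismatch_raises():
    tm = toy_transcript()
    ref = _genomic_base(tm, 120)
    wrong = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
    with pytest.raises(AnnotationError):
        annotate_coding_effect(("chr1", 120, wrong, "A" if wrong != "A" else "G"), tm)


def test_transcript_model_validation():
    with pytest.raises(ValueError):
        TranscriptModel("X", "c", "+", [(10, 5)], "AAA")
    with pytest.raises(ValueError):
        TranscriptModel("X", "c", "+", [(1, 3)], "AAAAAA")
    with pytest.warns(UserWarning):
        TranscriptModel("X", "c", "+", [(1, 4)], "AAAA")  # length % 3 != 0


# ---------------------------------------------------------------------------
# Filtering and ranking
# ---------------------------------------------------------------------------

def table1_fixture() -> pd.DataFrame:
    """The ten key interval variants as printed, positions schematic."""
    rows = [
        ("F1", 1001, "A", "G", "LY9", "synonymous", np.nan, 0.0, -5.0, 3.3, True, "synonymous"),
        ("F1", 1002, "A", "G", "LY9", "missense", np.nan, 0.0, -7.9, 3.3, True, "missense"),
        ("F1", 1003, "G", "A", "CD48", "missense", np.nan, 6.6, 2.1, 3.2, True, "missense"),
        ("F1", 1004, "C", "T", "SLAMF1", "synonymous", 0.018, 22.4, 2.3, 0.0, True, "missense"),
        ("F1", 1005, "GT", "G", "PEA15", "frameshift", np.nan, 29.7, 5.5, 1075.2, True, "frameshift"),
        ("F1", 1006, "C", "T", "ATP1A4", "synonymous", np.nan, np.nan, np.nan, 1.0, False, "synonymous"),
        ("F1", 1007, "C", "T", "ATP1A2", "synonymous", 0.044, 18.0, 2.8, 1224.9, True, "missense"),
        ("F1", 1008, "C", "T", "ATP1A2-IGSF8", "noncoding", 0.001, 21.1, 2.4, np.nan, True, "noncoding"),
        ("F1", 1009, "G", "A", "LOC101099681", "synonymous", 0.035, np.nan, np.nan, 0.0, False, "synonymous"),
        ("F1", 1010, "G", "A", "LOC101099681", "synonymous", 0.035, 0.7, -3.1, 0.0, True, "synonymous"),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene", "consequence", "af_population",
            "cadd", "gerp", "cpm_tissue", "liftover_ok", "cadd_basis_consequence",
        ],
    )


def test_key_interval_variants_rank_frameshift_first():
    ranked = filter_and_rank(table1_fixture())
    top = ranked.iloc[0]
    assert top["gene"] == "PEA15"
    assert top["consequence"] == "frameshift"
    assert top["af_label"] == "Absent"
    assert top["cadd_usable"] == pytest.approx(29.7)
    assert top["cpm_tissue"] == pytest.approx(1075.2)


def test_human_liftover_mismatch_flagged_and_excluded_from_cadd_order():
    ranked = filter_and_rank(table1_fixture())
    flagged = ranked[ranked["gene"].isin(["SLAMF1", "ATP1A2"])]
    assert flagged["flag_cadd_consequence_mismatch"].all()
    assert flagged["cadd_usable"].isna().all()
    # their (inflated) scores never lift them above unflagged coding variants
    cd48 = ranked.loc[ranked["gene"] == "CD48", "rank"].iloc[0]
    assert (flagged["rank"] > cd48).all()


def test_af_filter_boundary():
    df = table1_fixture()
    df.loc[df["gene"] == "ATP1A2", "af_population"] = 0.05  # at the boundary
    ranked = filter_and_rank(df, af_max=0.05)
    assert "ATP1A2" not in set(ranked["gene"])  # strict <


def test_ranking_matches_brute_force_sort_oracle():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = 30
        df = pd.DataFrame(
            {
                "chrom": rng.choice(["c1", "c2"], size=n),
                "pos": rng.choice(10_000, size=n, replace=False),
                "ref": "A",
                "alt": rng.choice(["G", "T"], size=n),
                "consequence": rng.choice(
                    ["synonymous", "missense", "frameshift", "other_lof", "noncoding"],
                    size=n,
                ),
                "af_population": np.where(
                    rng.random(n) < 0.3, np.nan, rng.uniform(0, 0.1, size=n)
                ),
                "cadd": np.where(rng.random(n) < 0.2, np.nan, rng.uniform(0, 40, n)),
                "gerp": rng.uniform(-8, 6, n),
                "cpm_tissue": rng.uniform(0, 10, n),
                "liftover_ok": rng.random(n) > 0.1,
            }
        )
        ranked = filter_and_rank(df)
        tier = {"frameshift": 3, "other_lof": 3, "missense": 2, "inframe": 2}

        def key(row):
            t = tier.get(row["consequence"], 1)
            cadd = row["cadd"] if row["liftover_ok"] and not np.isnan(row["cadd"]) else -1e9
            expressed = int(row["cpm_tissue"] >= 1.0)
            return (-t, -cadd, -expressed, row["chrom"], row["pos"], row["alt"])

        kept = df[df["af_population"].isna() | (df["af_population"] < 0.05)]
        expected = sorted(kept.to_dict("records"), key=key)
        got = ranked.sort_values("rank").to_dict("records")
        assert [(r["chrom"], r["pos"]) for r in got] == [
            (r["chrom"], r["pos"]) for r in expected
        ]


def test_ranking_invariant_to_input_order_and_stable_under_deletion():
    df = table1_fixture()
    base = filter_and_rank(df)
    shuffled = filter_and_rank(df.sample(frac=1.0, random_state=7))
    assert base[["chrom", "pos", "alt"]].equals(shuffled[["chrom", "pos", "alt"]])
    # removing the top candidate promotes the former second
    without_top = df[df["gene"] != "PEA15"]
    again = filter_and_rank(without_top)
    assert again.iloc[0][["chrom", "pos"]].tolist() == base.iloc[1][["chrom", "pos"]].tolist()


def test_empty_interval_gives_empty_list():
    out = filter_and_rank(table1_fixture().iloc[0:0])
    assert len(out) == 0


def test_planted_frameshift_ranks_first_on_synthetic_annotations(small_colony, small_cfg):
    _, hapset, geno = small_colony
    crow = hapset.sites.iloc[hapset.causal_index]
    lo, hi = small_cfg.segment_bounds
    sites = geno.sites[
        (geno.sites["chrom"] == small_cfg.causal_chromosome)
        & geno.sites["pos"].between(lo, hi)
    ].reset_index(drop=True)
    for seed in range(10):
        ann = cm.simulate_annotations(sites, (str(crow["chrom"]), int(crow["pos"])), seed=seed)
        ranked = filter_and_rank(ann)
        assert int(ranked.iloc[0]["pos"]) == int(crow["pos"])


# ---------------------------------------------------------------------------
# HWE extrapolation
# ---------------------------------------------------------------------------

def test_hwe_extrapolation_examples():
    assert hwe_extrapolate(0, 100, 1e9) == 0.0
    # 11 het carriers among 198,527 individuals, world population 7.7e9
    est = hwe_extrapolate(11, 198_527, 7.7e9)
    assert est == pytest.approx(5.9, abs=0.1)


def test_hwe_extrapolation_linear_in_population():
    a = hwe_extrapolate(7, 10_000, 1e9)
    b = hwe_extrapolate(7, 10_000, 2e9)
    assert b == pytest.approx(2 * a)


def test_hwe_extrapolation_errors():
    with pytest.raises(ValueError):
        hwe_extrapolate(1, 0, 1e9)
    with pytest.raises(ValueError):
        hwe_extrapolate(-1, 10, 1e9)
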