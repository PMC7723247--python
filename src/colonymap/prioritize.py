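"""Candidate-variant annotation, filtering and ranking in a critical interval.

Implements the evidence rules used to nominate a causal variant among the
variants of a fine-mapped recessive interval: consequence tier first
(frameshift and other loss-of-function above missense above synonymous or
noncoding), then deleteriousness score (CADD) among variants whose score is
trustworthy, with tissue expression as a tie-break and flag.  Scores whose
human-liftover consequence disagrees with the target-species consequence
(e.g. synonymous in the species, missense in human) are flagged and
excluded from ordering rather than allowed to inflate a candidate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CONSEQUENCES = ("synonymous", "missense", "frameshift", "other_lof", "noncoding", "inframe")

_TIER = {
    "frameshift": 3,
    "other_lof": 3,
    "missense": 2,
    "inframe": 2,
    "synonymous": 1,
    "noncoding": 1,
}

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AnnotationError(ValueError):
    """Variant inconsistent with the transcript model."""


@dataclass
class TranscriptModel:
    """Minimal CDS model: ordered, non-overlapping exon spans plus sequence.

    ``cds_sequence`` is the spliced coding sequence on the coding strand;
    exon coordinates are genomic, 1-based inclusive, ascending.
    """

    transcript_id: str
    chrom: str
    strand: str
    cds_exons: list[tuple[int, int]]
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        prev_end = 0
        for lo, hi in self.cds_exons:
            if lo > hi or lo <= prev_end:
                raise ValueError("CDS exons must be ordered and non-overlapping")
            prev_end = hi
        total = sum(hi - lo + 1 for lo, hi in self.cds_exons)
        if total != len(self.cds_sequence):
            raise ValueError(
                f"CDS sequence length {len(self.cds_sequence)} != exon total {total}"
            )
        if total % 3 != 0:
            warnings.warn(
                f"{self.transcript_id}: CDS length {total} not divisible by 3",
                stacklevel=2,
            )

    def cds_position(self, genomic_pos: int) -> int | None:
        """1-based coding-nucleotide index of a genomic position, or None."""
        offset = 0
        for lo, hi in self.cds_exons:
            if lo <= genomic_pos <= hi:
                within = genomic_pos - lo
                fwd = offset + within + 1
                if self.strand == "+":
                    return fwd
                total = sum(h - l + 1 for l, h in self.cds_exons)
                return total - fwd + 1
            offset += hi - lo + 1
        return None


def hgvs_codon_index(cds_position: int) -> int:
    """Codon containing a 1-based coding-nucleotide position.

    E.g. a deletion at coding position 176 first disrupts codon 59.
    """
    if cds_position < 1:
        raise ValueError(f"coding position must be >= 1, got {cds_position}")
    return (cds_position - 1) // 3 + 1


def annotate_coding_effect(
    variant: tuple[str, int, str, str], transcript: TranscriptModel
) -> str:
    """Classify a variant against a transcript model.

    Returns one of ``noncoding, synonymous, missense, other_lof,
    frameshift, inframe``.  Indels use VCF anchored-base convention; an
    indel whose length change is not a multiple of three within the CDS
    is a frameshift.  The variant's reference allele must agree with the
    transcript sequence.
    """
    chrom, pos, ref, alt = variant
    if chrom != transcript.chrom:
        return "noncoding"
    if len(ref) != len(alt):
        # anchored indel: affected bases start one past the anchor
        affected = range(pos + 1, pos + max(len(ref), len(alt)))
        in_cds = any(transcript.cds_position(p) is not None for p in affected) or (
            transcript.cds_position(pos) is not None
        )
        if not in_cds:
            return "noncoding"
        delta = abs(len(ref) - len(alt))
        return "frameshift" if delta % 3 else "inframe"
    if len(ref) != 1:
        raise AnnotationError(f"unsupported multi-nucleotide substitution {ref}>{alt}")
    cpos = transcript.cds_position(pos)
    if cpos is None:
        return "noncoding"
    ref_c, alt_c = ref, alt
    if transcript.strand == "-":
        ref_c = ref_c.translate(_COMPLEMENT)
        alt_c = alt_c.translate(_COMPLEMENT)
    seq = transcript.cds_sequence
    if seq[cpos - 1] != ref_c:
        raise AnnotationError(
            f"reference allele {ref} at {chrom}:{pos} (coding {cpos}) disagrees "
            f"with transcript base {seq[cpos - 1]}"
        )
    codon_i = hgvs_codon_index(cpos)
    start = (codon_i - 1) * 3
    codon = seq[start : start + 3]
    if len(codon) < 3:
        return "other_lof"  # truncated terminal codon; treat as damaging
    within = (cpos - 1) % 3
    alt_codon = codon[:within] + alt_c + codon[within + 1 :]
    aa_ref = _CODON_TABLE[codon]
    aa_alt = _CODON_TABLE[alt_codon]
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*" or aa_ref == "*":
        return "other_lof"
    return "missense"


def filter_and_rank(
    variants: pd.DataFrame,
    af_max: float = 0.05,
    expressed_cpm_min: float = 1.0,
) -> pd.DataFrame:
    """Filter interval variants by allele frequency and rank by evidence.

    Expects columns ``chrom, pos, ref, alt, consequence, af_population,
    cadd, gerp, cpm_tissue, liftover_ok`` and optionally
    ``cadd_basis_consequence`` (the human-liftover consequence the score
    derives from).  Missing ``af_population`` means absent from the
    frequency database (treated as 0, annotated "Absent").

    Ranking: consequence tier, then usable CADD descending (missing below
    present), then expressed-in-tissue flag, then (chrom, pos, alt) for a
    deterministic total order.
    """
    df = variants.copy().reset_index(drop=True)
    if df.empty:
        out = df.copy()
        out["rank"] = pd.Series(dtype=int)
        return out
    af = pd.to_numeric(df["af_population"], errors="coerce")
    keep = af.isna() | (af < af_max)
    df = df[keep].reset_index(drop=True)
    af = af[keep].reset_index(drop=True)

    basis = df.get("cadd_basis_consequence", df["consequence"])
    cadd = pd.to_numeric(df["cadd"], errors="coerce")
    mismatch = (
        (df["consequence"] == "synonymous")
        & (basis.isin(["missense", "frameshift", "other_lof"]))
        & cadd.notna()
    )
    liftover = df.get("liftover_ok", pd.Series(True, index=df.index)).fillna(False)
    cpm = pd.to_numeric(df["cpm_tissue"], errors="coerce")
    df["flag_cadd_consequence_mismatch"] = mismatch.to_numpy()
    df["flag_no_liftover"] = (~liftover).to_numpy()
    df["flag_not_expressed"] = (cpm.isna() | (cpm < expressed_cpm_min)).to_numpy()
    usable = cadd.where(~mismatch & liftover)
    df["cadd_usable"] = usable
    df["af_label"] = af.map(lambda v: "Absent" if pd.isna(v) else f"{v:.4g}")

    tier = df["consequence"].map(_TIER).fillna(1).astype(int)
    df["_tier"] = tier
    df["_expressed"] = (~df["flag_not_expressed"]).astype(int)
    df = df.sort_values(
        ["_tier", "cadd_usable", "_expressed", "chrom", "pos", "alt"],
        ascending=[False, False, False, True, True, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df = df.drop(columns=["_tier", "_expressed"])
    log.info("filter_and_rank: %d/%d variants kept after AF<%g filter",
             len(df), len(variants), af_max)
    return df


def hwe_extrapolate(
    n_het_carriers: int, n_individuals: int, population_size: float
) -> float:
    """Expected homozygote (or compound-het) carriers in a large population.

    Assumes Hardy-Weinberg, no observed homozygotes: allele frequency
    p = n_het / (2 n_individuals), expectation = population * p^2.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    if n_het_carriers < 0 or population_size < 0:
        raise ValueError("counts must be non-negative")
    p = n_het_carriers / (2.0 * n_individuals)
    return float(population_size * p * p)
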