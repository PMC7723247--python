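"""Readers and writers for the standard formats the pipeline touches.

VCF 4.2 (genotypes only), 6-column LINKAGE PED, and delimited tables.
Readers reject malformed input rather than silently coercing it; writers
produce deterministic byte output for a fixed input.  Internal coordinates
are 1-based inclusive (the VCF convention); BED export converts explicitly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import MISSING, GenotypeMatrix
from .pedigree import Individual, Pedigree, PedigreeError, Phenotype, Sex

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF 4.x into a :class:`GenotypeMatrix`.

    Multi-allelic records are decomposed into one biallelic row per alt
    allele; half calls and ``./.`` become missing.  Phase separators are
    ignored for dosage purposes.
    """
    path = str(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows: list[tuple[str, int, str, str]] = []
    dosages: list[np.ndarray] = []
    n_records = 0
    try:
        for var in vcf:
            n_records += 1
            gts = var.genotypes  # [[a0, a1, phased], ...]
            alleles = np.array(
                [[g[0], g[1]] for g in gts], dtype=np.int16
            )  # -1 for missing
            for ai, alt in enumerate(var.ALT, start=1):
                half_missing = (alleles < 0).any(axis=1)
                dos = (alleles == ai).sum(axis=1).astype(np.int8)
                dos[half_missing] = MISSING
                rows.append((var.CHROM, var.POS, var.REF, alt))
                dosages.append(dos)
    except Exception as exc:
        raise ParseError(
            f"malformed VCF record near record {n_records + 1} in {path}: {exc}"
        ) from exc
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosage = (
        np.vstack(dosages) if dosages else np.zeros((0, len(samples)), dtype=np.int8)
    )
    gm = GenotypeMatrix(sites, samples, dosage)
    log.info("read_vcf: %d sites x %d samples from %s", gm.n_sites, gm.n_samples, path)
    return gm


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as VCF 4.2.

    Genotypes are emitted as GT only; when the matrix carries haplotypes
    (``matrix.phased``) calls are written with phase bars.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in pd.unique(matrix.sites["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
    header = header[:8] + ["INFO"][:0]  # placeholder, fixed below
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    lines.append("\t".join(cols + list(matrix.samples)))
    unphased = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    for i in range(matrix.n_sites):
        site = matrix.sites.iloc[i]
        gts = []
        for j in range(matrix.n_samples):
            d = int(matrix.dosage[i, j])
            if matrix.phased is not None and d != -1:
                a, b = matrix.phased[i, j]
                gts.append(f"{a}|{b}")
            else:
                gts.append(unphased[d])
        lines.append(
            "\t".join(
                [
                    str(site["chrom"]),
                    str(int(site["pos"])),
                    ".",
                    str(site["ref"]),
                    str(site["alt"]),
                    ".",
                    ".",
                    ".",
                    "GT",
                ]
                + gts
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
    log.info("write_vcf: %d sites x %d samples -> %s", matrix.n_sites, matrix.n_samples, path)


# ---------------------------------------------------------------------------
# LINKAGE PED
# ---------------------------------------------------------------------------

_PHENO_CODE = {
    Phenotype.UNKNOWN: 0,
    Phenotype.UNAFFECTED: 1,
    Phenotype.AFFECTED: 2,
}


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 6-column LINKAGE PED file (family, id, sire, dam, sex, phenotype).

    Phenotype codes: 2 affected, 1 unaffected, 0 or -9 unknown.  Parsing is
    order-independent; structural invariants are validated after reading.
    """
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            dtype=str,
            comment="#",
        )
    except Exception as exc:
        raise ParseError(f"cannot parse PED {path}: {exc}") from exc
    if df.shape[1] < 6:
        raise ParseError(f"PED {path} has {df.shape[1]} columns, expected >= 6")
    df = df.iloc[:, :6]
    df.columns = ["fam", "iid", "sire", "dam", "sex", "pheno"]
    inds = []
    for ln, row in enumerate(df.itertuples(index=False), start=1):
        sire = None if row.sire in ("0", "") else row.sire
        dam = None if row.dam in ("0", "") else row.dam
        if row.sex not in ("1", "2"):
            raise ParseError(f"PED {path} line {ln}: bad sex code {row.sex!r}")
        if row.pheno not in ("0", "1", "2", "-9"):
            raise ParseError(f"PED {path} line {ln}: bad phenotype code {row.pheno!r}")
        pheno = {
            "2": Phenotype.AFFECTED,
            "1": Phenotype.UNAFFECTED,
            "0": Phenotype.UNKNOWN,
            "-9": Phenotype.UNKNOWN,
        }[row.pheno]
        inds.append(Individual(row.iid, sire, dam, Sex(int(row.sex)), pheno))
    fam = df["fam"].iloc[0] if len(df) else "COLONY"
    try:
        ped = Pedigree(inds, family_id=str(fam))
    except PedigreeError as exc:
        raise PedigreeError(f"invalid pedigree in {path}: {exc}") from exc
    log.info("read_pedigree: %d individuals from %s", len(ped), path)
    return ped


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    lines = []
    for ind in ped:
        lines.append(
            "\t".join(
                [
                    ped.family_id,
                    ind.iid,
                    ind.sire or "0",
                    ind.dam or "0",
                    str(ind.sex.value),
                    str(_PHENO_CODE[ind.phenotype]),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Delimited tables and BED export
# ---------------------------------------------------------------------------

def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except Exception as exc:
        raise ParseError(f"cannot parse table {path}: {exc}") from exc


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write 1-based inclusive intervals (chrom, start, end) as BED.

    BED is 0-based half-open, so start is shifted down by one.
    """
    out = intervals[["chrom"]].copy()
    out["start"] = intervals["start"].astype(int) - 1
    out["end"] = intervals["end"].astype(int)
    out.to_csv(path, sep="\t", header=False, index=False)
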