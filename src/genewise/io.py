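"""Readers and writers for the external formats.

Supported inputs: VCF with GT fields (via cyvcf2), a plain-text dosage
TSV (the package's internal interchange format), a phenotype TSV
(``sample_id<TAB>status`` with 1=control / 2=case) and BED4+ gene
annotations.  All outputs are TSV.
"""

from __future__ import annotations

import logging
import math
import os
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import CASE, CONTROL, GeneAnnotation, GenotypeDataset, SnpRecord

log = logging.getLogger(__name__)

_STATUS_TO_CODE = {"1": CONTROL, "2": CASE}


def read_phenotypes(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column phenotype TSV into ``{sample_id: 0/1}``.

    The status column follows the 1=control / 2=case convention of common
    GWAS tools.  A header line (``sample_id\\tstatus``) is optional.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"phenotype file not found: {path}")
    pheno: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            sid, status = parts[0].strip(), parts[1].strip()
            if lineno == 1 and status.lower() in {"status", "phenotype"}:
                continue  # header
            if status not in _STATUS_TO_CODE:
                raise ValueError(
                    f"{path}:{lineno}: status {status!r} not in {{1=control, 2=case}}"
                )
            if sid in pheno:
                raise ValueError(f"{path}:{lineno}: duplicate sample id {sid!r}")
            pheno[sid] = _STATUS_TO_CODE[status]
    return pheno


def read_genotypes_vcf(
    path: str | os.PathLike, phenotype_path: str | os.PathLike
) -> GenotypeDataset:
    """Read biallelic SNP genotypes from a VCF plus a phenotype TSV.

    Dosage is the alternate-allele count from GT.  Multi-allelic records
    and non-SNP variants are skipped (counted in the log).  Sample order
    is taken from the VCF header; samples absent from the phenotype file
    are dropped with a warning.
    """
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise FileNotFoundError(f"VCF not found: {path}")
    pheno = read_phenotypes(phenotype_path)

    vcf = VCF(str(path), gts012=True)
    vcf_samples = list(vcf.samples)
    keep = [i for i, s in enumerate(vcf_samples) if s in pheno]
    if not keep:
        raise ValueError("no overlap between VCF samples and phenotype file")
    dropped = len(vcf_samples) - len(keep)
    if dropped:
        log.warning("dropping %d VCF samples absent from the phenotype file", dropped)
    samples = [vcf_samples[i] for i in keep]

    snps: list[SnpRecord] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        gt = np.asarray(var.gt_types, dtype=np.float64)[keep]
        gt[gt == 3] = np.nan  # cyvcf2 gts012: 3 == unknown
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        snps.append(
            SnpRecord(
                snp_id=snp_id,
                chrom=var.CHROM,
                pos=var.POS - 1,  # VCF is 1-based
                allele_ref=var.REF,
                allele_alt=var.ALT[0],
            )
        )
        columns.append(gt)
    if n_skipped:
        log.info("skipped %d multi-allelic or non-SNP records", n_skipped)
    if not snps:
        raise ValueError(f"no biallelic SNP records found in {path}")
    dosages = np.column_stack(columns)
    phenotype = np.array([pheno[s] for s in samples], dtype=np.int8)
    return GenotypeDataset(snps=snps, samples=samples, dosages=dosages, phenotype=phenotype)


def read_genes_bed(path: str | os.PathLike) -> list[GeneAnnotation]:
    """Read gene intervals from a BED4+ file (0-based half-open, as BED)."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"BED not found: {path}")
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs >=4 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene name {name!r}")
            seen.add(name)
            genes.append(GeneAnnotation(gene_id=name, symbol=name, chrom=chrom, start=start, end=end))
    if not genes:
        log.warning("BED file %s contains no gene entries", path)
    return genes


def write_genes_bed(genes: Iterable[GeneAnnotation], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\n")


# ---------------------------------------------------------------------------
# internal dosage TSV: samples as rows, SNPs as columns.  The header token
# for each SNP column carries the full SNP identity so that the TSV reader
# and the VCF reader produce identical datasets for equivalent content.

def _snp_token(s: SnpRecord) -> str:
    return f"{s.snp_id}:{s.chrom}:{s.pos}:{s.allele_ref}:{s.allele_alt}"


def _parse_snp_token(token: str) -> SnpRecord:
    parts = token.split(":")
    if len(parts) != 5:
        raise ValueError(f"malformed SNP column header {token!r}")
    return SnpRecord(
        snp_id=parts[0], chrom=parts[1], pos=int(parts[2]),
        allele_ref=parts[3], allele_alt=parts[4],
    )


def write_dosage_tsv(data: GenotypeDataset, path: str | os.PathLike) -> None:
    """Write the internal dosage TSV (one row per sample; missing as NA)."""
    code_to_status = {CONTROL: "1", CASE: "2"}
    with open(path, "w") as fh:
        fh.write("sample_id\tstatus\t" + "\t".join(_snp_token(s) for s in data.snps) + "\n")
        for i, sid in enumerate(data.samples):
            row = data.dosages[i]
            cells = ["NA" if math.isnan(v) else str(int(v)) for v in row]
            fh.write(f"{sid}\t{code_to_status[data.phenotype[i]]}\t" + "\t".join(cells) + "\n")


def read_dosage_tsv(path: str | os.PathLike) -> GenotypeDataset:
    if not os.path.exists(path):
        raise FileNotFoundError(f"dosage TSV not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "status": str}, na_values=["NA"])
    if df.columns[0] != "sample_id" or df.columns[1] != "status":
        raise ValueError(f"{path}: expected leading columns sample_id, status")
    snps = [_parse_snp_token(c) for c in df.columns[2:]]
    dosages = df.iloc[:, 2:].to_numpy(dtype=np.float64)
    phenotype = np.array(
        [_STATUS_TO_CODE[s] for s in df["status"]], dtype=np.int8
    )
    return GenotypeDataset(
        snps=snps, samples=df["sample_id"].tolist(), dosages=dosages, phenotype=phenotype
    )


def write_phenotypes_tsv(data: GenotypeDataset, path: str | os.PathLike) -> None:
    code_to_status = {CONTROL: "1", CASE: "2"}
    with open(path, "w") as fh:
        fh.write("sample_id\tstatus\n")
        for sid, ph in zip(data.samples, data.phenotype):
            fh.write(f"{sid}\t{code_to_status[int(ph)]}\n")


# ---------------------------------------------------------------------------
# generic result tables

_P_COLUMNS = {"p", "p_emp", "p_uncontrolled", "p_maxT", "p_meanT", "p_topQ"}


def _format_p(value: float) -> str:
    return f"{value:.3e}"


def write_results_tsv(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a result table as TSV with p-values in scientific notation.

    Empirical p-values of genes whose observed score was never exceeded
    (``floor`` flag set) are written as ``<{1/N}``, i.e. the resolution
    floor of the permutation run, rather than as 0.
    """
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    out = table.copy()
    if "p_emp" in out.columns and "floor" in out.columns and "n_perm" in out.columns:
        formatted = []
        for p, fl, n in zip(out["p_emp"], out["floor"], out["n_perm"]):
            formatted.append(f"<{1.0 / n:.1e}" if fl else f"{p:.3e}")
        out["p_emp"] = formatted
    for col in out.columns:
        if col in _P_COLUMNS and out[col].dtype.kind == "f":
            out[col] = [_format_p(v) for v in out[col]]
    try:
        out.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"cannot write result table to {path}: {exc}") from exc
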