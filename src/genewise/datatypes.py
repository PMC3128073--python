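"""Core domain types shared by every stage of the pipeline.

Coordinates are 0-based half-open (BED-native) everywhere inside the
package; 1-based external formats (VCF positions, region strings as
printed in the literature) are converted at the I/O boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

#: phenotype codes used internally (the on-disk convention is 1=control, 2=case)
CONTROL = 0
CASE = 1


@dataclass(frozen=True)
class SnpRecord:
    """Identity of one biallelic SNP.

    ``pos`` is the 0-based coordinate of the variant site.
    """

    snp_id: str
    chrom: str
    pos: int
    allele_ref: str = "A"
    allele_alt: str = "G"

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"SNP {self.snp_id}: negative position {self.pos}")
        if self.allele_ref == self.allele_alt:
            raise ValueError(f"SNP {self.snp_id}: ref and alt alleles are identical")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval, 0-based half-open ``[start, end)``."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )


_REGION_RE = re.compile(r"^([\w.]+):([\d,]+)-([\d,]+)$")


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"region start {self.start} must be < end {self.end}")

    @classmethod
    def from_ucsc(cls, text: str) -> "GenomicRegion":
        """Parse ``chrom:start-end`` written 1-based inclusive (the common
        human-readable convention) into the internal 0-based half-open form."""
        m = _REGION_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end")
        chrom = m.group(1)
        start1 = int(m.group(2).replace(",", ""))
        end1 = int(m.group(3).replace(",", ""))
        return cls(chrom=chrom, start=start1 - 1, end=end1)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and max(self.start, start) < min(self.end, end)


@dataclass
class GenotypeDataset:
    """Case/control genotypes as an additive-dosage matrix.

    dosages : float array of shape (n_samples, n_snps) with values
        0/1/2 (count of alternate alleles) and NaN for missing calls.
    phenotype : int array with 1 for cases and 0 for controls, aligned
        with ``samples``.
    """

    snps: list[SnpRecord]
    samples: list[str]
    dosages: np.ndarray
    phenotype: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if self.phenotype.shape != (len(self.samples),):
            raise ValueError("phenotype length does not match samples")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids in dataset")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in dataset")
        labels = set(np.unique(self.phenotype).tolist())
        if not labels <= {CONTROL, CASE}:
            raise ValueError(f"phenotype codes must be 0/1, got {sorted(labels)}")
        if labels != {CONTROL, CASE}:
            raise ValueError("dataset needs at least one case and one control")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"dosage at sample {self.samples[bad[0]]}, SNP {ids[bad[1]]} "
                f"is {self.dosages[tuple(bad)]}; expected 0/1/2 or missing"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def is_case(self) -> np.ndarray:
        return self.phenotype == CASE

    @property
    def n_cases(self) -> int:
        return int((self.phenotype == CASE).sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == CONTROL).sum())

    def subset_snps(self, indices) -> "GenotypeDataset":
        """New dataset restricted to the SNP columns in ``indices`` (order kept)."""
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        return GenotypeDataset(
            snps=[self.snps[i] for i in indices],
            samples=list(self.samples),
            dosages=self.dosages[:, indices].copy(),
            phenotype=self.phenotype.copy(),
        )

    def snp_index(self) -> dict[str, int]:
        return {s.snp_id: i for i, s in enumerate(self.snps)}
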