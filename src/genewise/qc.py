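"""Per-SNP quality control on the pooled case/control dataset.

Filters (all computed on the pooled sample, before association testing):

* exact Hardy-Weinberg equilibrium test, remove if p < ``hwe_p_min``
* minor allele frequency, remove if MAF < ``maf_min`` (strictly less)
* genotype call rate, remove if < ``call_rate_min`` (strictly less)

The HWE test is the two-sided exact conditional test: conditional on the
observed allele counts, heterozygote counts whose probability does not
exceed that of the observed count contribute to the p-value.  No mid-p
adjustment is applied, so the test is well defined at low counts where
the chi-square approximation fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import GenotypeDataset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QcThresholds:
    hwe_p_min: float = 0.001
    maf_min: float = 0.01
    call_rate_min: float = 0.97

    def __post_init__(self) -> None:
        for name in ("hwe_p_min", "maf_min", "call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QcReport:
    """Per-SNP failure flags and removal tallies.

    A SNP may fail several criteria; each tally counts it once, and
    ``n_retained`` equals total minus the size of the union of failures.
    """

    flags: pd.DataFrame  # index snp_id; columns fail_hwe, fail_maf, fail_callrate
    n_total: int
    n_fail_hwe: int = 0
    n_fail_maf: int = 0
    n_fail_callrate: int = 0
    n_retained: int = 0

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": ["hwe", "maf", "call_rate", "retained", "total"],
                "n_snps": [
                    self.n_fail_hwe,
                    self.n_fail_maf,
                    self.n_fail_callrate,
                    self.n_retained,
                    self.n_total,
                ],
            }
        )


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for one biallelic SNP.

    Conditional on the allele counts, sums the probabilities of all
    heterozygote counts whose probability is <= that of the observed
    count.  Monomorphic sites admit a single configuration and return 1.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("all genotype counts are zero")
    n_alt = n_het + 2 * n_hom_alt
    n_ref = 2 * n - n_alt
    n_minor = min(n_ref, n_alt)
    if n_minor == 0:
        return 1.0

    # valid heterozygote counts share the parity of the minor allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # genotype counts implied by each het count (in terms of the alt allele)
    n_bb = (n_alt - hets) // 2
    n_aa = n - hets - n_bb
    log_p = (
        hets * np.log(2.0)
        - gammaln(n_aa + 1)
        - gammaln(hets + 1)
        - gammaln(n_bb + 1)
    )
    log_p -= log_p.max()
    probs = np.exp(log_p)
    probs /= probs.sum()
    obs = np.searchsorted(hets, n_het)
    if obs >= len(hets) or hets[obs] != n_het:
        raise ValueError(
            f"heterozygote count {n_het} impossible given allele counts"
        )
    p_obs = probs[obs]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def genotype_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (hom-ref, het, hom-alt) counts ignoring missing entries."""
    d = np.asarray(dosages)
    return (
        np.nansum(d == 0.0, axis=0).astype(int),
        np.nansum(d == 1.0, axis=0).astype(int),
        np.nansum(d == 2.0, axis=0).astype(int),
    )


def apply_snp_qc(
    data: GenotypeDataset,
    thresholds: QcThresholds = QcThresholds(),
    exclude_cases_for_hwe: bool = False,
) -> tuple[GenotypeDataset, QcReport]:
    """Remove SNPs failing any QC criterion; report tallies per criterion."""
    if data.n_snps < 1:
        raise ValueError("dataset contains no SNPs")
    d = data.dosages
    n_samples = data.n_samples
    non_missing = (~np.isnan(d)).sum(axis=0)
    call_rate = non_missing / n_samples
    with np.errstate(invalid="ignore"):
        p_alt = np.nansum(d, axis=0) / (2 * np.maximum(non_missing, 1))
    maf = np.minimum(p_alt, 1.0 - p_alt)

    hwe_source = d[data.phenotype == 0] if exclude_cases_for_hwe else d
    aa, ab, bb = genotype_counts(hwe_source)
    hwe_p = np.ones(data.n_snps)
    for j in range(data.n_snps):
        if aa[j] + ab[j] + bb[j] > 0:
            hwe_p[j] = hwe_exact_p(int(aa[j]), int(ab[j]), int(bb[j]))

    fail_hwe = hwe_p < thresholds.hwe_p_min
    fail_maf = maf < thresholds.maf_min
    fail_callrate = call_rate < thresholds.call_rate_min
    fail_any = fail_hwe | fail_maf | fail_callrate

    flags = pd.DataFrame(
        {
            "fail_hwe": fail_hwe,
            "fail_maf": fail_maf,
            "fail_callrate": fail_callrate,
            "hwe_p": hwe_p,
            "maf": maf,
            "call_rate": call_rate,
        },
        index=pd.Index(data.snp_ids, name="snp_id"),
    )
    report = QcReport(
        flags=flags,
        n_total=data.n_snps,
        n_fail_hwe=int(fail_hwe.sum()),
        n_fail_maf=int(fail_maf.sum()),
        n_fail_callrate=int(fail_callrate.sum()),
        n_retained=int((~fail_any).sum()),
    )
    if report.n_retained == 0:
        log.warning("no SNPs survive QC; returning an empty dataset")
        kept = data.subset_snps(np.array([], dtype=int))
        # bypass the >=1 SNP expectation downstream callers must handle
        return kept, report
    return data.subset_snps(~fail_any), report
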