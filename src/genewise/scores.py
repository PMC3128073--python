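"""Gene-wide summary statistics: maxT, meanT and topQ.

Given the per-SNP trend statistics T_1..T_n assigned to a gene:

* ``maxT``  -- the largest statistic;
* ``meanT`` -- the arithmetic mean;
* ``topQ``  -- the mean of the ceil(n/4) largest statistics (the top
  quartile, with the count rounded up: a 5-SNP gene averages its largest
  two statistics).

For any gene maxT >= topQ >= meanT, with equality at n = 1, and
topQ == maxT whenever n <= 4.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .assignment import AssignmentMap

log = logging.getLogger(__name__)

METHODS = ("maxT", "meanT", "topQ")


def top_quartile_count(n: int) -> int:
    """Number of statistics entering topQ: ceil(n/4)."""
    if n < 1:
        raise ValueError("gene must have at least one SNP")
    return -(-n // 4)


def score_gene(statistics, method: str) -> float:
    """Collapse one gene's statistics by the requested method."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    arr = np.asarray(statistics, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot score a gene with no statistics")
    if np.isnan(arr).any():
        raise ValueError(f"NaN statistic at position {int(np.flatnonzero(np.isnan(arr))[0])}")
    if method == "maxT":
        return float(arr.max())
    if method == "meanT":
        return float(arr.mean())
    k = top_quartile_count(arr.size)
    return float(np.sort(arr)[-k:].mean())


def score_all_genes(
    assoc: pd.DataFrame,
    amap: AssignmentMap,
    stat_col: str = "T_corrected",
) -> pd.DataFrame:
    """One row of (n, maxT, meanT, topQ) per gene.

    SNPs in the map but absent from ``assoc`` (typically removed by QC)
    are pruned first; genes losing all SNPs are dropped and counted in
    the log.
    """
    if stat_col not in assoc.columns:
        raise ValueError(f"association table lacks column {stat_col!r}")
    stat_by_snp = dict(zip(assoc["snp_id"], assoc[stat_col].to_numpy(dtype=np.float64)))
    rows = []
    n_dropped = 0
    for gene_id, snp_list in amap.gene_to_snps.items():
        present = [s for s in snp_list if s in stat_by_snp]
        if not present:
            n_dropped += 1
            continue
        stats = np.array([stat_by_snp[s] for s in present])
        for s, v in zip(present, stats):
            if math.isnan(v):
                raise ValueError(f"NaN statistic for SNP {s} in gene {gene_id}")
        k = top_quartile_count(stats.size)
        part = np.partition(stats, stats.size - k)
        rows.append(
            {
                "gene_id": gene_id,
                "n": stats.size,
                "k_top": k,
                "maxT": float(stats.max()),
                "meanT": float(stats.mean()),
                "topQ": float(part[stats.size - k:].mean()),
            }
        )
    if n_dropped:
        log.info("%d genes dropped: all their SNPs were pruned", n_dropped)
    return pd.DataFrame(rows, columns=["gene_id", "n", "k_top", "maxT", "meanT", "topQ"])
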