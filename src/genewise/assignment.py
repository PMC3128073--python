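"""SNP-to-gene assignment with a flanking window, exclusion regions, and
optional extension through linkage disequilibrium.

Base rule: a SNP is eligible for a gene if it lies within the gene body
or within ``window_bp`` (default 40 kb) up- or downstream; among several
eligible genes the closest wins (distance 0 inside the gene, otherwise
base pairs to the nearer boundary), with alphabetical gene id as the
deterministic tie-break.  High-LD regions such as the MHC can be excluded
up front: both SNPs inside and genes overlapping an excluded region are
removed before assignment.

LD extension adds, in a single step, every SNP whose squared dosage
correlation with a SNP already assigned to a gene exceeds ``r2_min``
(default 0.8); after extension a SNP may belong to several genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .datatypes import GeneAnnotation, GenomicRegion, GenotypeDataset, SnpRecord

log = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 40_000

#: the classical MHC exclusion interval on chromosome 6 (GRCh37), given
#: 1-based inclusive as usually printed and converted to 0-based half-open
MHC_REGION_GRCH37 = GenomicRegion(chrom="6", start=25_930_838, end=33_495_825)


@dataclass
class AssignmentMap:
    """Gene <-> SNP mapping.

    ``pairs`` has one row per (gene_id, snp_id, source) with source
    ``window`` for the base distance rule and ``ld`` for LD-added SNPs.
    In base mode each SNP maps to at most one gene.
    """

    pairs: pd.DataFrame
    window_bp: int = DEFAULT_WINDOW_BP

    def __post_init__(self) -> None:
        required = {"gene_id", "snp_id", "source"}
        if not required <= set(self.pairs.columns):
            raise ValueError(f"pairs frame needs columns {sorted(required)}")
        if self.pairs.duplicated(["gene_id", "snp_id"]).any():
            raise ValueError("duplicate (gene, SNP) pair in assignment map")

    @property
    def gene_to_snps(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, s in zip(self.pairs["gene_id"], self.pairs["snp_id"]):
            out.setdefault(g, []).append(s)
        return out

    @property
    def snp_to_genes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, s in zip(self.pairs["gene_id"], self.pairs["snp_id"]):
            out.setdefault(s, []).append(g)
        return out

    @property
    def n_per_gene(self) -> pd.Series:
        return self.pairs.groupby("gene_id", sort=False)["snp_id"].size()

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.pairs["gene_id"]))

    @property
    def n_assigned_snps(self) -> int:
        return self.pairs["snp_id"].nunique()

    def prune_to(self, snp_ids: Iterable[str]) -> "AssignmentMap":
        """Drop SNPs not in ``snp_ids`` (e.g. removed by QC); genes left
        with no SNPs disappear from the map."""
        keep = set(snp_ids)
        pruned = self.pairs[self.pairs["snp_id"].isin(keep)].reset_index(drop=True)
        n_lost = len(self.genes) - pruned["gene_id"].nunique()
        if n_lost:
            log.info("%d genes lost all SNPs after pruning", n_lost)
        return AssignmentMap(pairs=pruned, window_bp=self.window_bp)

    def to_frame(self) -> pd.DataFrame:
        return self.pairs.copy()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, window_bp: int = DEFAULT_WINDOW_BP) -> "AssignmentMap":
        return cls(pairs=frame.reset_index(drop=True), window_bp=window_bp)


@dataclass
class LdPairs:
    """SNP pairs above an r-squared threshold within a pairing window."""

    pairs: pd.DataFrame  # columns snp_a, snp_b, r2
    r2_min: float = 0.8
    max_window_bp: int = 1_000_000

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {}
        for a, b in zip(self.pairs["snp_a"], self.pairs["snp_b"]):
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return adj


def _distance(pos: int, start: int, end: int) -> int:
    """0 inside [start, end); otherwise bp to the nearer boundary."""
    if start <= pos < end:
        return 0
    if pos < start:
        return start - pos
    return pos - end + 1


def assign_snps(
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneAnnotation],
    window_bp: int = DEFAULT_WINDOW_BP,
    exclude: Sequence[GenomicRegion] = (),
) -> AssignmentMap:
    """Assign each SNP to its closest gene within ``window_bp``."""
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")

    kept_genes = [
        g for g in genes
        if not any(r.overlaps(g.chrom, g.start, g.end) for r in exclude)
    ]
    kept_snps = [
        s for s in snps if not any(r.contains(s.chrom, s.pos) for r in exclude)
    ]
    if exclude:
        log.info(
            "exclusion regions removed %d SNPs and %d genes",
            len(snps) - len(kept_snps), len(genes) - len(kept_genes),
        )

    trees: dict[str, IntervalTree] = {}
    gene_by_id: dict[str, GeneAnnotation] = {}
    for g in kept_genes:
        if g.gene_id in gene_by_id:
            raise ValueError(f"duplicate gene id {g.gene_id!r}")
        gene_by_id[g.gene_id] = g
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start - window_bp, g.end + window_bp, g.gene_id
        )

    records: list[tuple[str, str]] = []
    for s in kept_snps:
        tree = trees.get(s.chrom)
        if tree is None:
            continue
        hits = tree[s.pos]
        if not hits:
            continue
        best = min(
            (
                (_distance(s.pos, gene_by_id[iv.data].start, gene_by_id[iv.data].end), iv.data)
                for iv in hits
            ),
        )
        records.append((best[1], s.snp_id))
    if not records:
        log.warning("no SNPs could be assigned to any gene")
    pairs = pd.DataFrame(records, columns=["gene_id", "snp_id"])
    pairs["source"] = "window"
    # stable, reproducible ordering regardless of input gene order
    pairs = pairs.sort_values(["gene_id", "snp_id"], kind="mergesort").reset_index(drop=True)
    return AssignmentMap(pairs=pairs, window_bp=window_bp)


def compute_ld_pairs(
    data: GenotypeDataset,
    r2_min: float = 0.8,
    max_window_bp: int = 1_000_000,
) -> LdPairs:
    """All same-chromosome SNP pairs within ``max_window_bp`` whose squared
    dosage correlation (composite LD, phase-free) exceeds ``r2_min``.

    Correlation is over samples non-missing at both SNPs; monomorphic
    SNPs contribute no pairs.
    """
    if data.n_snps < 2:
        raise ValueError("need at least 2 SNPs to compute LD")
    D = data.dosages
    has_missing = bool(np.isnan(D).any())
    ids = data.snp_ids
    chroms = np.array([s.chrom for s in data.snps])
    pos = np.array([s.pos for s in data.snps])

    rows: list[tuple[str, str, float]] = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        idx = idx[np.argsort(pos[idx], kind="mergesort")]
        if idx.size < 2:
            continue
        p = pos[idx]
        sub = D[:, idx]
        if not has_missing:
            centered = sub - sub.mean(axis=0)
            norms = np.sqrt((centered * centered).sum(axis=0))
            ok = norms > 0
            with np.errstate(invalid="ignore", divide="ignore"):
                Z = np.where(ok, centered / np.where(ok, norms, 1.0), 0.0)
            for a in range(idx.size - 1):
                if not ok[a]:
                    continue
                hi = np.searchsorted(p, p[a] + max_window_bp, side="right")
                js = np.arange(a + 1, hi)
                js = js[ok[js]]
                if js.size == 0:
                    continue
                r2 = (Z[:, a] @ Z[:, js]) ** 2
                for j, v in zip(js[r2 > r2_min], r2[r2 > r2_min]):
                    rows.append((ids[idx[a]], ids[idx[j]], float(v)))
        else:
            for a in range(idx.size - 1):
                hi = np.searchsorted(p, p[a] + max_window_bp, side="right")
                for b in range(a + 1, hi):
                    da, db = sub[:, a], sub[:, b]
                    m = ~np.isnan(da) & ~np.isnan(db)
                    if m.sum() < 2:
                        continue
                    xa, xb = da[m] - da[m].mean(), db[m] - db[m].mean()
                    va, vb = (xa * xa).sum(), (xb * xb).sum()
                    if va <= 0 or vb <= 0:
                        continue
                    r2 = float((xa @ xb) ** 2 / (va * vb))
                    if r2 > r2_min:
                        rows.append((ids[idx[a]], ids[idx[b]], r2))
    frame = pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])
    return LdPairs(pairs=frame, r2_min=r2_min, max_window_bp=max_window_bp)


def extend_assignment_ld(base: AssignmentMap, ld: LdPairs) -> AssignmentMap:
    """Single-step LD extension of a base assignment.

    Every SNP in LD with a SNP *currently* assigned to gene g is added to
    g (no transitive closure through newly added SNPs).  SNPs already
    assigned elsewhere are added too, so genes may share SNPs afterwards.
    """
    adj = ld.adjacency()
    new_rows: list[tuple[str, str, str]] = []
    for gene_id, snp_list in base.gene_to_snps.items():
        current = set(snp_list)
        added: set[str] = set()
        for s in snp_list:
            added |= adj.get(s, set())
        for s in sorted(added - current):
            new_rows.append((gene_id, s, "ld"))
    if not new_rows:
        return AssignmentMap(pairs=base.pairs.copy(), window_bp=base.window_bp)
    extended = pd.concat(
        [base.pairs, pd.DataFrame(new_rows, columns=["gene_id", "snp_id", "source"])],
        ignore_index=True,
    )
    extended = extended.sort_values(["gene_id", "snp_id"], kind="mergesort").reset_index(drop=True)
    return AssignmentMap(pairs=extended, window_bp=base.window_bp)
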