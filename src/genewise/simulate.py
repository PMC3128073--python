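"""Synthetic case/control cohorts with block LD and skewed gene sizes.

The generator emulates the features a gene-level GWAS method actually
exercises, without aiming for full population-genetic realism:

* **Block LD** — the genome is partitioned into haplotype blocks; each
  block carries a small founder pool of binary haplotypes (allele
  frequencies Beta-distributed) and every individual draws two founder
  haplotypes per block.  A limited founder count induces within-block
  correlation between SNPs; blocks are mutually independent.
* **Skewed gene sizes** — per-gene SNP counts follow a geometric body
  plus a long tail, so most genes carry fewer than 10 SNPs while a small
  fraction carries more than 50, mimicking the strongly right-skewed
  distribution of SNPs per gene on genotyping arrays.
* **Planted effects** — optional causal SNPs act through a logistic
  disease model (log-odds = intercept + sum of per-allele log odds
  ratios x dosage); case/control quotas are filled by rejection
  sampling, and the truth set is the list of genes containing causal
  SNPs.

Genes are tiled along chromosomes with inter-gene gaps larger than
twice the assignment window, so the distance-based SNP-to-gene
assignment recovers exactly the simulated gene memberships.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import expit, logit

from .datatypes import GeneAnnotation, GenotypeDataset, SnpRecord
from . import io as gio

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CausalGene:
    """A planted effect: ``n_snps`` causal SNPs inside gene ``gene_index``,
    each with the same per-allele odds ratio."""

    gene_index: int
    n_snps: int = 1
    odds_ratio: float = 1.5

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")
        if self.n_snps < 1:
            raise ValueError("need at least one causal SNP")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a desk-scale cohort: 500 cases + 500 controls,
    ~300 genes totalling ~2,000 SNPs, moderate block LD from a 20-founder
    haplotype pool, and a common-disease prevalence of 10%.
    """

    n_cases: int = 500
    n_controls: int = 500
    n_genes: int = 300
    gene_size_mean: float = 4.0        # geometric mean of the small-gene body
    gene_size_tail_frac: float = 0.08  # fraction of genes drawn from the tail
    gene_size_tail_offset: int = 15
    gene_size_tail_mean: float = 25.0  # geometric mean added on top of the offset
    snps_per_block_mean: float = 8.0
    n_founder_haplotypes: int = 20
    maf_beta_params: tuple[float, float] = (1.2, 3.0)
    maf_min: float = 0.05
    window_bp: int = 40_000
    snp_spacing_bp: int = 1_000
    inter_gene_gap_bp: int = 100_000
    genes_per_chrom: int = 50
    causal_genes: tuple[CausalGene, ...] = ()
    prevalence: float = 0.1
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_genes) < 1:
            raise ValueError("counts must be positive")
        a, b = self.maf_beta_params
        if a <= 0 or b <= 0:
            raise ValueError("Beta parameters must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        for c in self.causal_genes:
            if not 0 <= c.gene_index < self.n_genes:
                raise ValueError(f"causal gene index {c.gene_index} out of range")

    def to_yaml(self, path: str | os.PathLike) -> None:
        payload = dataclasses.asdict(self)
        payload["causal_genes"] = [dataclasses.asdict(c) for c in self.causal_genes]
        payload["maf_beta_params"] = list(self.maf_beta_params)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        payload["causal_genes"] = tuple(
            CausalGene(**c) for c in payload.get("causal_genes", [])
        )
        if "maf_beta_params" in payload:
            payload["maf_beta_params"] = tuple(payload["maf_beta_params"])
        return cls(**payload)


def with_planted_signal(
    cfg: SimulationConfig,
    n_causal_genes: int = 10,
    or_min: float = 1.5,
    or_max: float = 2.0,
    n_snps_each: int = 1,
) -> SimulationConfig:
    """Plant causal genes at evenly spaced gene indices with odds ratios
    spread linearly across [or_min, or_max]."""
    idx = np.linspace(0, cfg.n_genes - 1, n_causal_genes).round().astype(int)
    ors = np.linspace(or_min, or_max, n_causal_genes)
    causal = tuple(
        CausalGene(gene_index=int(i), n_snps=n_snps_each, odds_ratio=float(o))
        for i, o in zip(idx, ors)
    )
    return dataclasses.replace(cfg, causal_genes=causal)


# ---------------------------------------------------------------------------
# layout


def _draw_gene_sizes(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    body = rng.geometric(1.0 / cfg.gene_size_mean, size=cfg.n_genes)
    tail = cfg.gene_size_tail_offset + rng.geometric(
        1.0 / cfg.gene_size_tail_mean, size=cfg.n_genes
    )
    in_tail = rng.random(cfg.n_genes) < cfg.gene_size_tail_frac
    return np.where(in_tail, tail, body).astype(int)


def _draw_block_sizes(total_snps: int, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    sizes: list[int] = []
    covered = 0
    while covered < total_snps:
        s = int(rng.geometric(1.0 / cfg.snps_per_block_mean))
        sizes.append(min(s, total_snps - covered))
        covered += sizes[-1]
    return np.array(sizes, dtype=int)


def simulate_haplotype_blocks(
    cfg: SimulationConfig, rng: np.random.Generator, n_snps: int | None = None
) -> list[dict]:
    """Founder haplotype pool per LD block.

    Each block holds ``n_founder_haplotypes`` binary haplotypes over its
    SNPs, with per-SNP allele frequencies drawn from the Beta model and
    clipped away from 0/1.  If ``n_snps`` is omitted it is drawn from the
    gene-size distribution, consuming the rng exactly as
    :func:`simulate_cohort` does.
    """
    if n_snps is None:
        n_snps = int(_draw_gene_sizes(cfg, rng).sum())
    block_sizes = _draw_block_sizes(n_snps, cfg, rng)
    a, b = cfg.maf_beta_params
    blocks = []
    for m in block_sizes:
        freqs = np.clip(rng.beta(a, b, size=m), cfg.maf_min, 1.0 - cfg.maf_min)
        founders = (rng.random((cfg.n_founder_haplotypes, m)) < freqs).astype(np.uint8)
        blocks.append({"freqs": freqs, "founders": founders})
    return blocks


# ---------------------------------------------------------------------------
# cohort


def _genotype_batch(blocks: list[dict], batch: int, rng: np.random.Generator) -> np.ndarray:
    cols = []
    for blk in blocks:
        founders = blk["founders"]
        i1 = rng.integers(founders.shape[0], size=batch)
        i2 = rng.integers(founders.shape[0], size=batch)
        cols.append(founders[i1] + founders[i2])
    return np.concatenate(cols, axis=1).astype(np.float64)


def simulate_cohort(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeDataset, list[GeneAnnotation], set[str]]:
    """Simulate one cohort: genotypes + phenotypes, gene annotations and
    the truth set of causal genes."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    sizes = _draw_gene_sizes(cfg, rng)
    total_snps = int(sizes.sum())
    blocks = simulate_haplotype_blocks(cfg, rng, n_snps=total_snps)
    freqs = np.concatenate([b["freqs"] for b in blocks])

    # physical layout: genes tiled along chromosomes, gaps > 2x window
    gene_first = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    positions = np.empty(total_snps, dtype=int)
    chroms: list[str] = [""] * total_snps
    genes: list[GeneAnnotation] = []
    cursor = 1_000_000
    for g in range(cfg.n_genes):
        chrom = f"chr{g // cfg.genes_per_chrom + 1}"
        if g % cfg.genes_per_chrom == 0:
            cursor = 1_000_000
        lo, hi = gene_first[g], gene_first[g] + sizes[g]
        for k, j in enumerate(range(lo, hi)):
            positions[j] = cursor + k * cfg.snp_spacing_bp
            chroms[j] = chrom
        gene_end = positions[hi - 1] + 1
        genes.append(
            GeneAnnotation(
                gene_id=f"G{g:04d}", symbol=f"G{g:04d}",
                chrom=chrom, start=int(positions[lo]), end=int(gene_end),
            )
        )
        cursor = gene_end + cfg.inter_gene_gap_bp

    # causal SNPs and the logistic disease model; a causal SNP must
    # segregate in the founder pool, so candidates are restricted to
    # sites with realized minor-allele frequency >= 0.1 (falling back to
    # the most polymorphic site in the gene)
    pool_freq = np.concatenate([b["founders"].mean(axis=0) for b in blocks])
    pool_maf = np.minimum(pool_freq, 1.0 - pool_freq)
    causal_idx: list[int] = []
    causal_beta: list[float] = []
    truth: set[str] = set()
    for c in cfg.causal_genes:
        lo, hi = gene_first[c.gene_index], gene_first[c.gene_index] + sizes[c.gene_index]
        span = np.arange(lo, hi)
        candidates = span[pool_maf[span] >= 0.1]
        if candidates.size == 0:
            candidates = span[[int(np.argmax(pool_maf[span]))]]
        n_pick = min(c.n_snps, candidates.size)
        picks = rng.choice(candidates, size=n_pick, replace=False)
        causal_idx.extend(int(p) for p in picks)
        causal_beta.extend([float(np.log(c.odds_ratio))] * n_pick)
        truth.add(genes[c.gene_index].gene_id)
    causal_idx_arr = np.array(causal_idx, dtype=int)
    beta = np.array(causal_beta)
    intercept = float(
        logit(cfg.prevalence) - (beta * 2.0 * pool_freq[causal_idx_arr]).sum()
    )

    # rejection sampling until both quotas are met
    need_cases, need_controls = cfg.n_cases, cfg.n_controls
    case_rows: list[np.ndarray] = []
    control_rows: list[np.ndarray] = []
    drawn = 0
    max_draws = 200 * (cfg.n_cases + cfg.n_controls) + 10_000
    while need_cases > 0 or need_controls > 0:
        if drawn >= max_draws:
            raise RuntimeError(
                "case/control quota unattainable: odds ratios and prevalence "
                f"inconsistent after {drawn} draws"
            )
        batch = min(4096, max_draws - drawn)
        D = _genotype_batch(blocks, batch, rng)
        drawn += batch
        eta = np.full(batch, intercept)
        if causal_idx_arr.size:
            eta = eta + D[:, causal_idx_arr] @ beta
        is_case = rng.random(batch) < expit(eta)
        if need_cases > 0:
            take = D[is_case][:need_cases]
            case_rows.append(take)
            need_cases -= take.shape[0]
        if need_controls > 0:
            take = D[~is_case][:need_controls]
            control_rows.append(take)
            need_controls -= take.shape[0]

    dosages = np.concatenate(
        [np.concatenate(case_rows, axis=0), np.concatenate(control_rows, axis=0)], axis=0
    )
    phenotype = np.concatenate(
        [np.ones(cfg.n_cases, dtype=np.int8), np.zeros(cfg.n_controls, dtype=np.int8)]
    )
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = np.nan

    snps = [
        SnpRecord(
            snp_id=f"rs{j:06d}", chrom=chroms[j], pos=int(positions[j]),
            allele_ref="A", allele_alt="G",
        )
        for j in range(total_snps)
    ]
    samples = [f"S{i:05d}" for i in range(cfg.n_cases + cfg.n_controls)]
    data = GenotypeDataset(snps=snps, samples=samples, dosages=dosages, phenotype=phenotype)
    return data, genes, truth


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixture(
    data: GenotypeDataset,
    genes: list[GeneAnnotation],
    truth: set[str],
    out_dir: str | os.PathLike,
) -> dict[str, str]:
    """Write VCF + phenotype TSV + BED + truth list, readable by the
    package's own readers.  Returns the paths written."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "phenotypes": os.path.join(out_dir, "phenotypes.tsv"),
        "bed": os.path.join(out_dir, "genes.bed"),
        "truth": os.path.join(out_dir, "truth.txt"),
    }
    _write_vcf(data, paths["vcf"])
    gio.write_phenotypes_tsv(data, paths["phenotypes"])
    gio.write_genes_bed(genes, paths["bed"])
    with open(paths["truth"], "w") as fh:
        for g in sorted(truth):
            fh.write(g + "\n")
    return paths


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def _write_vcf(data: GenotypeDataset, path: str | os.PathLike) -> None:
    contigs = list(dict.fromkeys(s.chrom for s in data.snps))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=genewise-simulate\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(data.samples) + "\n")
        for j, s in enumerate(data.snps):
            col = data.dosages[:, j]
            gts = "\t".join(
                "./." if np.isnan(v) else _GT[v] for v in col
            )
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t{s.snp_id}\t{s.allele_ref}\t"
                f"{s.allele_alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )
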