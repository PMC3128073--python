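"""Ranking, method concordance, uncontrolled p-values and ROC/AUC.

Genes are ranked by empirical p-value with the gene-wide statistic as
tie-break (so genes at the permutation resolution floor are ordered by
their observed statistic).  ROC curves treat a supplied truth gene list
as positives and every other ranked gene as a negative; the area under
the trapezoid curve equals the Mann-Whitney probability that a random
positive outranks a random negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, spearmanr

log = logging.getLogger(__name__)


def rank_genes(results: pd.DataFrame) -> pd.DataFrame:
    """Rank one method's empirical results (1 = most significant).

    Sort key: p_emp ascending, observed statistic descending, gene id
    alphabetical for residual ties.
    """
    required = {"gene_id", "p_emp", "observed"}
    if not required <= set(results.columns):
        raise ValueError(f"results need columns {sorted(required)}")
    if "method" in results.columns and results["method"].nunique() > 1:
        raise ValueError("rank_genes expects results for a single method")
    if results["gene_id"].duplicated().any():
        dup = results.loc[results["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id {dup!r} in results")
    ranked = results.sort_values(
        by=["p_emp", "observed", "gene_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked


def rank_by_statistic(scores: pd.DataFrame, method: str) -> pd.DataFrame:
    """Uncontrolled ranking: by the gene-wide statistic alone (equivalent
    to sorting by the chi-square-converted p-value)."""
    frame = pd.DataFrame(
        {
            "gene_id": scores["gene_id"],
            "p_emp": chi2.sf(scores[method].to_numpy(dtype=float), df=1),
            "observed": scores[method].to_numpy(dtype=float),
        }
    )
    return rank_genes(frame)


def uncontrolled_pvalues(scores: pd.DataFrame, method: str) -> pd.Series:
    """Upper-tail chi-square(1 df) probability of the gene-wide statistic,
    deliberately ignoring the number of SNPs behind it."""
    vals = scores[method].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("non-finite gene score")
    return pd.Series(chi2.sf(vals, df=1), index=scores["gene_id"], name=f"p_{method}")


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_positives: int
    n_negatives: int

    def points(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def roc_curve(ranking: pd.DataFrame, positives: set[str]) -> RocCurve:
    """ROC of a ranked gene list against a truth set.

    Stepping down the ranking, each positive raises TPR by 1/P and each
    negative raises FPR by 1/(G-P); AUC is the trapezoid area.
    """
    genes = ranking.sort_values("rank")["gene_id"].tolist()
    pos = set(positives) & set(genes)
    if not pos:
        raise ValueError("no overlap between positives and ranked genes")
    n_pos = len(pos)
    n_neg = len(genes) - n_pos
    if n_neg == 0:
        raise ValueError("need at least one negative gene")
    is_pos = np.array([g in pos for g in genes])
    tpr = np.concatenate([[0.0], np.cumsum(is_pos) / n_pos])
    fpr = np.concatenate([[0.0], np.cumsum(~is_pos) / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc, n_positives=n_pos, n_negatives=n_neg)


def null_auc_quantile(
    n_genes: int,
    n_positives: int,
    q: float = 0.95,
    n_draws: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Quantile of the AUC distribution under random ranking, by drawing
    random rank positions for the positives."""
    if rng is None:
        rng = np.random.default_rng(0)
    n_neg = n_genes - n_positives
    aucs = np.empty(n_draws)
    for i in range(n_draws):
        ranks = rng.choice(n_genes, size=n_positives, replace=False) + 1
        # Mann-Whitney from ranks (rank 1 = best)
        aucs[i] = (np.sum(n_genes + 1 - ranks) - n_positives * (n_positives + 1) / 2) / (
            n_positives * n_neg
        )
    return float(np.quantile(aucs, q))


def method_concordance(
    rankings: dict[str, pd.DataFrame], top_k: int
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Spearman correlation between ranked gene lists.

    Genes are selected by their best (smallest) rank sum across all the
    supplied lists; the ``top_k`` most consistently significant genes
    enter the correlation.  Returns the correlation matrix and the
    selected genes.
    """
    if top_k < 3:
        raise ValueError("top_k must be >= 3")
    names = list(rankings)
    if len(names) < 2:
        raise ValueError("need at least two rankings")
    universes = [set(r["gene_id"]) for r in rankings.values()]
    if any(u != universes[0] for u in universes[1:]):
        raise ValueError("rankings cover different gene universes")
    if top_k > len(universes[0]):
        raise ValueError("top_k exceeds the number of genes")
    rank_mat = pd.DataFrame(
        {name: r.set_index("gene_id")["rank"] for name, r in rankings.items()}
    )
    rank_sum = rank_mat.sum(axis=1)
    selected = rank_sum.sort_values(kind="mergesort").index[:top_k].tolist()
    sub = rank_mat.loc[selected]
    mat = np.ones((len(names), len(names)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rho = spearmanr(sub[names[i]], sub[names[j]]).statistic
            mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat, index=names, columns=names), selected
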