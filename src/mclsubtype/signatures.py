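"""Gene-set signature scoring from TPM expression and cluster comparison.

A sample's signature value for a gene set is the mean of log2(TPM + 1)
over the set's genes present in the matrix (the +1 pseudocount handles
zeros; set genes absent from the matrix are dropped with a log message,
duplicates deduplicated). Cluster signature values are the arithmetic
means of member samples' scores; a one-way F test compares the score
distributions across clusters, and cluster means are additionally min-max
scaled to [0, 1] for display (raw means are always retained).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .encoding import LesionMatrix

logger = logging.getLogger(__name__)


def _validate_tpm(tpm: pd.DataFrame) -> None:
    if (tpm.to_numpy() < 0).any():
        raise ValueError("TPM values must be nonnegative")
    if tpm.columns.duplicated().any():
        raise ValueError("duplicate sample ids in expression matrix")


def signature_score(tpm: pd.DataFrame, gene_set: list[str], name: str = "signature") -> pd.Series:
    """Per-sample mean log2(TPM+1) over the gene set."""
    _validate_tpm(tpm)
    genes = list(dict.fromkeys(gene_set))  # dedupe, order-preserving
    present = [g for g in genes if g in tpm.index]
    if not present:
        raise ValueError(f"no genes of set {name!r} found in the expression matrix")
    if len(present) < len(genes):
        logger.info("gene set %s: %d of %d genes absent from the matrix, dropped",
                    name, len(genes) - len(present), len(genes))
    return np.log2(tpm.loc[present] + 1.0).mean(axis=0).rename(name)


def score_gene_sets(tpm: pd.DataFrame, gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Samples x gene-sets score table."""
    return pd.concat(
        [signature_score(tpm, genes, name) for name, genes in gene_sets.items()], axis=1
    )


def compare_clusters(scores: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-gene-set cluster means and one-way F test across clusters.

    Clusters with fewer than 2 samples are excluded with a warning.
    Returns one row per gene set with the F statistic, p-value, raw
    per-cluster means (``mean_<cluster>``) and the min-max scaled means
    (``scaled_<cluster>``).
    """
    labels = labels.loc[scores.index]
    counts = labels.value_counts()
    small = counts[counts < 2].index
    if len(small):
        warnings.warn(f"clusters excluded with <2 samples: {sorted(small)}", stacklevel=2)
    keep = sorted(counts[counts >= 2].index)
    if len(keep) < 2:
        raise ValueError("cluster comparison needs >= 2 clusters with >= 2 samples")

    rows = []
    for name in scores.columns:
        groups = [scores.loc[labels == c, name].to_numpy() for c in keep]
        f_stat, p = stats.f_oneway(*groups)
        means = np.array([g.mean() for g in groups])
        span = means.max() - means.min()
        scaled = (means - means.min()) / span if span > 0 else np.zeros_like(means)
        row = {"GeneSet": name, "F": float(f_stat), "P": float(p)}
        row.update({f"mean_{c}": m for c, m in zip(keep, means)})
        row.update({f"scaled_{c}": s for c, s in zip(keep, scaled)})
        rows.append(row)
    return pd.DataFrame(rows)


def deletion_expression_check(
    tpm: pd.DataFrame,
    lesion_matrix: LesionMatrix,
    lesion: str,
    region_genes: list[str],
) -> pd.DataFrame:
    """Expression effect of a copy-number lesion on the genes it covers.

    For each region gene present in the matrix: difference in mean
    log2(TPM+1) between carrier samples (lesion score >= 1) and
    non-carriers, a rank-sum (Mann-Whitney U) p-value, BH q across the
    region genes, and a direction flag ('down' for negative effects, the
    expected direction for deletions).
    """
    _validate_tpm(tpm)
    if not region_genes:
        raise ValueError("region gene list is empty")
    shared_samples = [s for s in tpm.columns if s in lesion_matrix.scores.index]
    carriers_mask = lesion_matrix.scores.loc[shared_samples, lesion] >= 1
    carriers = [s for s, m in zip(shared_samples, carriers_mask) if m]
    others = [s for s, m in zip(shared_samples, carriers_mask) if not m]
    if not carriers:
        raise ValueError(f"no carrier samples for lesion {lesion!r}")
    if not others:
        raise ValueError(f"all samples carry lesion {lesion!r}; no comparison group")

    present = [g for g in dict.fromkeys(region_genes) if g in tpm.index]
    if not present:
        raise ValueError("none of the region genes are in the expression matrix")
    log_expr = np.log2(tpm.loc[present] + 1.0)
    rows = []
    for gene in present:
        a = log_expr.loc[gene, carriers].to_numpy()
        b = log_expr.loc[gene, others].to_numpy()
        effect = float(a.mean() - b.mean())
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"Gene": gene, "Effect": effect, "P": float(p)})
    table = pd.DataFrame(rows)
    _, q, _, _ = multipletests(table["P"], method="fdr_bh")
    table["Q"] = q
    table["Direction"] = np.where(table["Effect"] < 0, "down", "up")
    return table
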