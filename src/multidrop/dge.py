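"""Differential-expression stability under multiplet removal.

A cluster-pair contrast is tested twice — once on all droplets and once after
dropping multiplets — and the two result sets are compared by the Jaccard
index of their significant-gene sets and the Spearman correlation of log2 fold
changes over the union of significant genes.  The built-in test is a Wilcoxon
rank-sum on log-normalized counts; externally computed DE tables (gene,
log2fc, pval) can be ingested instead, since the comparison protocol is
test-agnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu, spearmanr
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "StabilitySummary",
    "filter_genes",
    "de_test",
    "bh_adjust",
    "compare_de_runs",
    "FDR_THRESHOLD",
    "LFC_THRESHOLD",
]

FDR_THRESHOLD = 0.05
LFC_THRESHOLD = 0.5


@dataclass(frozen=True)
class StabilitySummary:
    """Agreement between two DE runs on the same contrast.

    ``jaccard``: overlap of significant gene sets; ``spearman``: rank
    correlation of log2FC over the union of genes significant in either run
    (NaN when the union has < 2 genes); ``n_union``: size of that union.
    """

    jaccard: float
    spearman: float
    n_union: int


def filter_genes(counts: ad.AnnData, min_frac: float = 0.05) -> pd.Index:
    """Genes expressed (nonzero) in at least ``ceil(min_frac * n)`` droplets."""
    n = counts.n_obs
    if n == 0:
        raise ValidationError("count matrix has no droplets")
    X = counts.X
    nnz = (
        np.asarray((X != 0).sum(axis=0)).ravel()
        if sp.issparse(X)
        else np.count_nonzero(np.asarray(X), axis=0)
    )
    return counts.var_names[nnz >= math.ceil(min_frac * n)]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(pvals, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _log_normalize(X: np.ndarray, target_sum: float = 1e4) -> np.ndarray:
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(X / totals * target_sum)


def de_test(
    counts: ad.AnnData,
    group_a: Sequence[str],
    group_b: Sequence[str],
    genes: pd.Index | None = None,
    fdr_threshold: float = FDR_THRESHOLD,
    lfc_threshold: float = LFC_THRESHOLD,
) -> pd.DataFrame:
    """Two-group differential expression with the first group as reference.

    Counts are CP10K + log1p normalized per droplet; each gene gets a
    two-sided Wilcoxon rank-sum p-value and a fold change
    ``log2((mean_B + 1) / (mean_A + 1))`` of de-logged (CP10K-scale) group
    means.  P-values are BH-adjusted and a gene is significant when
    FDR < ``fdr_threshold`` and |log2FC| > ``lfc_threshold``.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValidationError("each group needs at least 3 droplets")
    missing = (set(group_a) | set(group_b)) - set(counts.obs_names)
    if missing:
        raise ValidationError(f"{len(missing)} group droplets absent from the matrix")
    if genes is None:
        genes = counts.var_names
    sub = counts[group_a + group_b, list(genes)]
    X = np.asarray(sub.X.todense() if sp.issparse(sub.X) else sub.X, dtype=float)
    logX = _log_normalize(X)
    a = logX[: len(group_a)]
    b = logX[len(group_a):]

    with np.errstate(invalid="ignore"):
        res = mannwhitneyu(a, b, alternative="two-sided", axis=0, method="asymptotic")
        pvals = np.asarray(res.pvalue, dtype=float)
    # constant genes: tie-corrected variance is 0 -> NaN; no evidence either way
    pvals = np.where(np.isnan(pvals), 1.0, pvals)

    mean_a = np.expm1(a).mean(axis=0)
    mean_b = np.expm1(b).mean(axis=0)
    log2fc = np.log2((mean_b + 1.0) / (mean_a + 1.0))
    fdr = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pval": pvals,
            "fdr": fdr,
            "significant": (fdr < fdr_threshold) & (np.abs(log2fc) > lfc_threshold),
        },
        index=pd.Index(list(genes), name="gene_id"),
    )


def compare_de_runs(run1: pd.DataFrame, run2: pd.DataFrame) -> StabilitySummary:
    """Jaccard of significant sets and Spearman of log2FC over their union.

    Both runs must carry ``log2fc`` and ``significant`` columns on a shared
    gene universe.  Jaccard is 1.0 when both significant sets are empty;
    Spearman is NaN when the union holds fewer than 2 genes.
    """
    for df in (run1, run2):
        if not {"log2fc", "significant"} <= set(df.columns):
            raise ValidationError("DE results need 'log2fc' and 'significant' columns")
    shared = run1.index.intersection(run2.index)
    if len(shared) == 0:
        raise ValidationError("runs share no genes")
    sig1 = set(run1.loc[shared].index[run1.loc[shared, "significant"]])
    sig2 = set(run2.loc[shared].index[run2.loc[shared, "significant"]])
    union = sig1 | sig2
    jaccard = 1.0 if not union else len(sig1 & sig2) / len(union)
    if len(union) >= 2:
        u = sorted(union)
        rho = float(spearmanr(run1.loc[u, "log2fc"], run2.loc[u, "log2fc"]).statistic)
    else:
        rho = float("nan")
    return StabilitySummary(jaccard=float(jaccard), spearman=rho, n_union=len(union))
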