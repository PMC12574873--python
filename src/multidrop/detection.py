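"""Evaluation of per-droplet multiplet scores against hashing quasi-ground-truth.

Detection tools assign every droplet a score (higher = more multiplet-like).
Scores are evaluated against cell-hashing labels by AUPRC (average precision)
and AUROC, parameter settings are selected by AUPRC, and multiplets are called
as the top-scored droplets at an assumed rate.  Called sets are compared via
exclusive (UpSet-style) intersection counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import ValidationError

__all__ = [
    "ScoreSet",
    "CallSet",
    "auprc",
    "auroc",
    "select_best_params",
    "call_multiplets_at_rate",
    "remove_called",
    "intersection_counts",
    "per_cluster_composition",
]


@dataclass(frozen=True)
class ScoreSet:
    """Named method's per-droplet multiplet scores (higher = more multiplet-like)."""

    method: str
    scores: pd.Series

    def __post_init__(self) -> None:
        if not self.scores.index.is_unique:
            raise ValidationError(f"{self.method}: droplet ids must be unique")
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValidationError(f"{self.method}: scores must be finite")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class CallSet:
    """Droplets flagged multiplet by one method at an assumed rate."""

    method: str
    called: frozenset
    assumed_rate: float


def _aligned(scores: ScoreSet, labels) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(labels, pd.Series):
        missing = scores.scores.index.difference(labels.index)
        if len(missing):
            raise ValidationError(f"labels missing for {len(missing)} scored droplets")
        y = labels.reindex(scores.scores.index).to_numpy()
    else:
        y = np.asarray(labels)
        if y.shape[0] != len(scores):
            raise ValidationError("labels length must match scores")
    y = y.astype(bool)
    if y.all() or not y.any():
        raise ValidationError("labels must contain at least one positive and one negative")
    return scores.scores.to_numpy(dtype=float), y


def auprc(scores: ScoreSet, labels) -> float:
    """Area under the precision-recall curve (average precision, ties grouped)."""
    s, y = _aligned(scores, labels)
    return float(average_precision_score(y, s))


def auroc(scores: ScoreSet, labels) -> float:
    """Area under the ROC curve: P(score_pos > score_neg) + 0.5 P(tie)."""
    s, y = _aligned(scores, labels)
    return float(roc_auc_score(y, s))


def select_best_params(
    candidates: Sequence[tuple[object, ScoreSet]], labels
) -> object:
    """Return the parameter setting whose scores maximize AUPRC (first wins ties)."""
    if len(candidates) == 0:
        raise ValidationError("need at least one candidate setting")
    best_setting, best_val = None, -np.inf
    for setting, scoreset in candidates:
        val = auprc(scoreset, labels)
        if val > best_val:
            best_setting, best_val = setting, val
    return best_setting


def call_multiplets_at_rate(scores: ScoreSet, rate: float) -> CallSet:
    """Flag the top-scored droplets corresponding to an assumed multiplet rate.

    ``k = round(rate * n)`` (half-up) droplets are called; boundary ties are
    broken by lexicographic droplet id for determinism.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValidationError(f"rate must lie in [0, 1], got {rate!r}")
    n = len(scores)
    k = int(np.floor(rate * n + 0.5))
    ids = scores.scores.index.to_numpy()
    vals = scores.scores.to_numpy(dtype=float)
    order = np.lexsort((ids, -vals))  # score desc, id asc
    return CallSet(method=scores.method, called=frozenset(ids[order[:k]]), assumed_rate=float(rate))


def remove_called(counts: ad.AnnData, calls: CallSet) -> ad.AnnData:
    """Drop called droplets from the matrix; the gene set is unchanged."""
    unknown = calls.called - set(counts.obs_names)
    if unknown:
        raise ValidationError(
            f"{calls.method}: {len(unknown)} called droplets absent from the matrix"
        )
    keep = ~counts.obs_names.isin(calls.called)
    return counts[keep].copy()


def intersection_counts(
    callsets: Mapping[str, Iterable], top_n: int | None = 20
) -> list[tuple[tuple[str, ...], int]]:
    """Exclusive (UpSet-style) intersection sizes over the power set of methods.

    Each droplet in the union contributes to exactly one membership pattern.
    Patterns with nonzero counts are returned sorted by count descending
    (pattern lexicographic on ties), truncated to ``top_n`` (None = all).
    """
    if len(callsets) == 0:
        raise ValidationError("need at least one call set")
    sets = {m: frozenset(s) for m, s in callsets.items()}
    union = frozenset().union(*sets.values())
    patterns: dict[tuple[str, ...], int] = {}
    for d in union:
        pat = tuple(sorted(m for m, s in sets.items() if d in s))
        patterns[pat] = patterns.get(pat, 0) + 1
    out = sorted(patterns.items(), key=lambda kv: (-kv[1], kv[0]))
    return out if top_n is None else out[:top_n]


def per_cluster_composition(
    labels: pd.Series, clusters: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster x {multiplet, singlet} percentage matrices.

    Returns ``(column_normalized, row_normalized)``: in the first, each class
    column sums to 100 (how a method's multiplets distribute across clusters);
    in the second, each cluster row sums to 100 (within-cluster multiplet
    fraction).
    """
    labels = pd.Series(labels)
    clusters = pd.Series(clusters)
    if not labels.index.equals(clusters.index):
        if set(labels.index) != set(clusters.index):
            raise ValidationError("labels and clusters must cover the same droplets")
        clusters = clusters.reindex(labels.index)
    classes = labels.astype(bool).map({True: "multiplet", False: "singlet"})
    table = pd.crosstab(clusters, classes).reindex(columns=["multiplet", "singlet"], fill_value=0)
    col_totals = table.sum(axis=0)
    col_pct = table.div(col_totals.replace(0, np.nan), axis=1).fillna(0.0) * 100.0
    row_pct = table.div(table.sum(axis=1), axis=0) * 100.0
    return col_pct, row_pct
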