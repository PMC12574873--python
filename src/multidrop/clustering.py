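"""Light clustering pipeline, quality metrics, subsampling protocol, rank aggregation.

Dataset versions (full matrix vs matrices with multiplets removed by different
methods) are clustered with a standard normalize -> HVG -> PCA -> kNN ->
Louvain pipeline and compared on three internal quality metrics
(Calinski-Harabasz, Davies-Bouldin, silhouette).  Because versions differ in
size, metrics are computed on repeated stratified subsamples of fixed size
using the original cluster assignments (no reclustering), and versions are
ranked by median metric value with a small (0.1-weighted) penalty on
interquartile-range rank to reward consistency.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass

import anndata as ad
import igraph
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)
from sklearn.neighbors import NearestNeighbors

from .errors import ValidationError

__all__ = [
    "ClusterAssignment",
    "Correspondence",
    "preprocess_and_cluster",
    "silhouette_value",
    "calinski_harabasz",
    "davies_bouldin",
    "stratified_subsample",
    "metrics_under_subsampling",
    "aggregate_ranks",
    "cluster_correspondence",
]

METRICS = ("calinski_harabasz", "davies_bouldin", "silhouette")
# lower Davies-Bouldin is better; the other two are higher-is-better
_HIGHER_IS_BETTER = {"calinski_harabasz": True, "davies_bouldin": False, "silhouette": True}


@dataclass(frozen=True)
class ClusterAssignment:
    """Cluster label per droplet for one dataset version."""

    labels: pd.Series
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.labels.index.is_unique:
            raise ValidationError("droplet ids must be unique")
        uniq = np.unique(self.labels.to_numpy())
        if len(uniq) and not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValidationError("cluster labels must be contiguous integers from 0")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


@dataclass(frozen=True)
class Correspondence:
    """Cluster overlap before/after droplet removal, over shared droplets.

    ``counts``: rows = post-removal clusters, columns = pre-removal clusters,
    entries = shared droplet counts.  ``jaccard``: same shape,
    |i & j| / |i | j| per cluster pair.
    """

    counts: pd.DataFrame
    jaccard: pd.DataFrame


def _relabel_by_size(membership: np.ndarray) -> np.ndarray:
    """Map community ids to 0..C-1 by decreasing size (ties: first appearance)."""
    ids, first, sizes = np.unique(membership, return_index=True, return_counts=True)
    order = np.lexsort((first, -sizes))
    mapping = np.empty(ids.max() + 1, dtype=int)
    mapping[ids[order]] = np.arange(len(ids))
    return mapping[membership]


def preprocess_and_cluster(
    counts: ad.AnnData,
    n_hvg: int = 2000,
    n_pcs: int = 10,
    n_neighbors: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
    provenance: str = "",
) -> tuple[np.ndarray, ClusterAssignment]:
    """Normalize, select HVGs, embed with PCA, and Louvain-cluster a kNN graph.

    Steps: total-count normalization to 10,000 + log1p; top ``n_hvg`` genes by
    variance of the normalized values; z-scaling; PCA to ``n_pcs``; kNN graph
    (k = ``n_neighbors``); Louvain communities at the given resolution.
    Deterministic under a fixed seed.  Returns the PCA embedding and the
    assignment with labels renumbered by decreasing cluster size.
    """
    n = counts.n_obs
    if n < 2:
        raise ValidationError("need at least 2 droplets")
    if n < n_pcs + 1:
        raise ValidationError(f"need more droplets ({n}) than principal components ({n_pcs})")
    adata = counts.copy()
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)

    X = adata.X
    if sp.issparse(X):
        mean = np.asarray(X.mean(axis=0)).ravel()
        mean_sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    else:
        X = np.asarray(X)
        mean = X.mean(axis=0)
        mean_sq = (X**2).mean(axis=0)
    var = np.maximum(mean_sq - mean**2, 0.0)

    # all droplets identical -> one cluster, degenerate embedding
    if var.max() <= 1e-12 * max(1.0, float(mean_sq.max())):
        labels = pd.Series(0, index=counts.obs_names, name="cluster")
        return np.zeros((n, 1)), ClusterAssignment(labels=labels, provenance=provenance)

    n_hvg = min(n_hvg, int((var > 0).sum()))
    hvg = np.sort(np.argsort(var)[::-1][:n_hvg])
    Xh = X[:, hvg]
    Xh = np.asarray(Xh.todense()) if sp.issparse(Xh) else np.asarray(Xh)
    Xh = (Xh - mean[hvg]) / np.sqrt(var[hvg])

    n_comp = min(n_pcs, n - 1, Xh.shape[1])
    emb = PCA(n_components=n_comp, random_state=seed).fit_transform(Xh)

    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    src = np.repeat(np.arange(n), k)
    dst = idx[:, 1:].ravel()
    g = igraph.Graph(n=n, edges=list(zip(src.tolist(), dst.tolist())), directed=False)
    g.simplify()
    # python-igraph draws from Python's random module by default
    _pyrandom.seed(seed)
    membership = np.asarray(g.community_multilevel(resolution=resolution).membership)
    labels = pd.Series(_relabel_by_size(membership), index=counts.obs_names, name="cluster")
    return emb, ClusterAssignment(labels=labels, provenance=provenance)


def _check_metric_input(embedding: np.ndarray, labels) -> tuple[np.ndarray, np.ndarray]:
    y = labels.labels.to_numpy() if isinstance(labels, ClusterAssignment) else np.asarray(labels)
    X = np.asarray(embedding)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("embedding and labels must have matching length")
    if len(np.unique(y)) < 2:
        raise ValidationError("clustering quality metrics require >= 2 clusters")
    return X, y


def silhouette_value(embedding: np.ndarray, labels) -> float:
    """Mean silhouette over droplets (closer to 1 is better)."""
    X, y = _check_metric_input(embedding, labels)
    return float(silhouette_score(X, y))


def calinski_harabasz(embedding: np.ndarray, labels) -> float:
    """Between/within dispersion ratio (higher is better)."""
    X, y = _check_metric_input(embedding, labels)
    return float(calinski_harabasz_score(X, y))


def davies_bouldin(embedding: np.ndarray, labels) -> float:
    """Mean maximal pairwise cluster similarity (lower is better)."""
    X, y = _check_metric_input(embedding, labels)
    return float(davies_bouldin_score(X, y))


def _quotas(sizes: np.ndarray, n_target: int) -> np.ndarray:
    """Largest-remainder apportionment of n_target by cluster proportions.

    Leftover seats go to the largest remainders; remainder ties go to the
    larger cluster, then the smaller label.
    """
    n = sizes.sum()
    exact = n_target * sizes / n
    base = np.floor(exact).astype(int)
    leftover = n_target - base.sum()
    rem = exact - base
    order = np.lexsort((np.arange(len(sizes)), -sizes, -rem))
    quotas = base.copy()
    quotas[order[:leftover]] += 1
    return quotas


def stratified_subsample(
    labels, n_target: int, n_iter: int = 100, seed: int = 0
) -> list[np.ndarray]:
    """Repeated without-replacement subsamples preserving cluster composition.

    Per-cluster quotas follow largest-remainder apportionment of
    ``n_target`` x cluster proportions and sum exactly to ``n_target``.
    Returns ``n_iter`` sorted positional index arrays.
    """
    y = labels.labels.to_numpy() if isinstance(labels, ClusterAssignment) else np.asarray(labels)
    n = y.shape[0]
    if n_target > n:
        raise ValidationError(f"n_target={n_target} exceeds droplet count {n}")
    uniq, sizes = np.unique(y, return_counts=True)
    quotas = _quotas(sizes, n_target)
    over = quotas > sizes
    if over.any():
        raise ValidationError(
            f"cluster {uniq[over][0]} smaller than its quota ({sizes[over][0]} < {quotas[over][0]})"
        )
    rng = np.random.default_rng(seed)
    members = [np.flatnonzero(y == c) for c in uniq]
    out = []
    for _ in range(n_iter):
        picks = [rng.choice(m, size=q, replace=False) for m, q in zip(members, quotas)]
        out.append(np.sort(np.concatenate(picks)))
    return out


def metrics_under_subsampling(
    embedding: np.ndarray,
    labels,
    n_target: int,
    n_iter: int = 100,
    seed: int = 0,
    dataset: str = "dataset",
    version: str = "version",
) -> pd.DataFrame:
    """Quality metrics on stratified subsamples, keeping the original labels.

    No reclustering is performed: metrics are evaluated on the subsampled
    embedding with the existing cluster assignment, isolating the effect of
    droplet removal from that of dataset size.  Returns a long-form table
    (dataset, version, metric, iteration, value).
    """
    X, y = _check_metric_input(embedding, labels)
    records = []
    fns = {
        "calinski_harabasz": calinski_harabasz_score,
        "davies_bouldin": davies_bouldin_score,
        "silhouette": silhouette_score,
    }
    for it, idx in enumerate(stratified_subsample(y, n_target, n_iter=n_iter, seed=seed)):
        for metric, fn in fns.items():
            records.append(
                {
                    "dataset": dataset,
                    "version": version,
                    "metric": metric,
                    "iteration": it,
                    "value": float(fn(X[idx], y[idx])),
                }
            )
    return pd.DataFrame.from_records(records)


def aggregate_ranks(table: pd.DataFrame, metrics=None) -> pd.Series:
    """Direction-aware average rank per version with an IQR consistency penalty.

    Within each (dataset, metric) cell, versions are ranked by median value in
    the metric's preferred direction (descending for silhouette and
    Calinski-Harabasz, ascending for Davies-Bouldin; ties get mean ranks) and
    their interquartile ranges are ranked ascending.  The combined score is
    ``performance rank + 0.1 * IQR rank``; the returned value per version is
    the mean combined score over all (dataset, metric) cells.  Pass
    ``metrics=["silhouette"]`` for the silhouette-only aggregation.
    """
    required = {"dataset", "version", "metric", "value"}
    if not required <= set(table.columns):
        raise ValidationError(f"metric table must have columns {sorted(required)}")
    if metrics is not None:
        table = table[table["metric"].isin(metrics)]
        if table.empty:
            raise ValidationError(f"no rows for metrics {metrics}")
    versions = sorted(table["version"].unique())
    if len(versions) < 2:
        return pd.Series(1.0, index=pd.Index(versions, name="version"), name="average_rank")
    combined: dict[str, list[float]] = {v: [] for v in versions}
    for (ds, metric), cell in table.groupby(["dataset", "metric"], sort=True):
        got = set(cell["version"].unique())
        if got != set(versions):
            raise ValidationError(
                f"missing versions {sorted(set(versions) - got)} in ({ds}, {metric})"
            )
        med = cell.groupby("version")["value"].median().loc[versions]
        q1 = cell.groupby("version")["value"].quantile(0.25).loc[versions]
        q3 = cell.groupby("version")["value"].quantile(0.75).loc[versions]
        vals = med.to_numpy()
        perf = rankdata(-vals if _HIGHER_IS_BETTER[metric] else vals, method="average")
        iqr_rank = rankdata((q3 - q1).to_numpy(), method="average")
        for v, p, q in zip(versions, perf, iqr_rank):
            combined[v].append(p + 0.1 * q)
    out = pd.Series(
        {v: float(np.mean(c)) for v, c in combined.items()}, name="average_rank"
    ).sort_values()
    out.index.name = "version"
    return out


def cluster_correspondence(pre: ClusterAssignment, post: ClusterAssignment) -> Correspondence:
    """Shared-droplet counts and Jaccard similarity between pre/post clusters.

    Comparison is restricted to droplets present in both assignments (removal
    only drops droplets).  Row sums of ``counts`` equal post-cluster sizes and
    column sums equal pre-cluster sizes, both over shared droplets.
    """
    shared = pre.labels.index.intersection(post.labels.index)
    if len(shared) == 0:
        raise ValidationError("assignments share no droplets")
    pre_y = pre.labels.loc[shared]
    post_y = post.labels.loc[shared]
    counts = pd.crosstab(post_y, pre_y)
    counts.index.name = "post_cluster"
    counts.columns.name = "pre_cluster"
    col_sizes = counts.sum(axis=0)
    row_sizes = counts.sum(axis=1)
    union = np.add.outer(row_sizes.to_numpy(), col_sizes.to_numpy()) - counts.to_numpy()
    jaccard = pd.DataFrame(
        counts.to_numpy() / union, index=counts.index, columns=counts.columns
    )
    return Correspondence(counts=counts, jaccard=jaccard)
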