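"""Clustering pipeline, quality metrics, subsampling, rank aggregation, correspondence."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from multidrop import (
    ClusterAssignment,
    ValidationError,
    aggregate_ranks,
    calinski_harabasz,
    cluster_correspondence,
    davies_bouldin,
    metrics_under_subsampling,
    preprocess_and_cluster,
    silhouette_value,
    stratified_subsample,
)


def assignment(labels, ids=None, provenance="test"):
    ids = ids if ids is not None else [f"d{i:03d}" for i in range(len(labels))]
    return ClusterAssignment(labels=pd.Series(labels, index=ids), provenance=provenance)


@pytest.fixture(scope="module")
def clustered(two_type_sim):
    _, truth, _, counts = two_type_sim
    emb, asg = preprocess_and_cluster(counts, n_hvg=200, n_pcs=10, seed=0)
    return counts, emb, asg


class TestPreprocessAndCluster:
    def test_recovers_generating_types_on_singlets(self, two_type_sim):
        _, truth, _, counts = two_type_sim
        singlet = counts.obs["k"].to_numpy() == 1
        singlets = counts[singlet].copy()
        true_type = np.array(
            [
                truth.cell_type[truth.cell_droplet == i][0]
                for i in np.flatnonzero(singlet)
            ]
        )
        _, asg = preprocess_and_cluster(singlets, n_hvg=200, n_pcs=10, seed=0)
        assert adjusted_rand_score(true_type, asg.labels.to_numpy()) == 1.0

    def test_deterministic(self, two_type_sim):
        _, _, _, counts = two_type_sim
        emb1, a1 = preprocess_and_cluster(counts, n_hvg=200, seed=3)
        emb2, a2 = preprocess_and_cluster(counts, n_hvg=200, seed=3)
        assert np.array_equal(emb1, emb2)
        assert a1.labels.equals(a2.labels)

    def test_identical_rows_single_cluster(self):
        import anndata as ad

        X = np.tile([3, 1, 0, 2], (30, 1))
        adata = ad.AnnData(X=X.astype(np.int64))
        emb, asg = preprocess_and_cluster(adata, n_pcs=2)
        assert asg.n_clusters == 1

    def test_labels_contiguous_and_sorted_by_size(self, clustered):
        asg = clustered[2]
        sizes = asg.labels.value_counts().sort_index()
        assert list(sizes.index) == list(range(asg.n_clusters))
        assert list(sizes) == sorted(sizes, reverse=True)

    def test_too_few_droplets_rejected(self):
        import anndata as ad

        adata = ad.AnnData(X=np.eye(4, dtype=np.int64))
        with pytest.raises(ValidationError):
            preprocess_and_cluster(adata, n_pcs=10)


class TestQualityMetrics:
    # hand-computed oracle: clusters {(0,0),(0,1)} and {(10,0),(10,1)}
    POINTS = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
    LABELS = np.array([0, 0, 1, 1])

    def test_silhouette_hand_value(self):
        expected = 1.0 - 2.0 / (10.0 + np.sqrt(101.0))
        assert silhouette_value(self.POINTS, self.LABELS) == pytest.approx(expected)

    def test_calinski_harabasz_hand_value(self):
        # BGSS = 100, WGSS = 1, k = 2, n = 4 -> (100/1)/(1/2) = 200
        assert calinski_harabasz(self.POINTS, self.LABELS) == pytest.approx(200.0)

    def test_davies_bouldin_hand_value(self):
        # S_i = 0.5, centroid distance 10 -> R = 0.1
        assert davies_bouldin(self.POINTS, self.LABELS) == pytest.approx(0.1)

    def test_label_permutation_invariance(self):
        relabeled = np.array([1, 1, 0, 0])
        for fn in (silhouette_value, calinski_harabasz, davies_bouldin):
            assert fn(self.POINTS, self.LABELS) == pytest.approx(fn(self.POINTS, relabeled))

    def test_well_separated_blobs(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (50, 3)), rng.normal(100, 0.3, (50, 3))])
        y = np.repeat([0, 1], 50)
        assert silhouette_value(X, y) > 0.99

    def test_single_cluster_rejected(self):
        for fn in (silhouette_value, calinski_harabasz, davies_bouldin):
            with pytest.raises(ValidationError):
                fn(self.POINTS, np.zeros(4, dtype=int))


class TestStratifiedSubsample:
    def test_equal_clusters_equal_quotas(self):
        y = np.repeat([0, 1], 50)
        for idx in stratified_subsample(y, 50, n_iter=5, seed=0):
            assert len(idx) == 50
            assert (y[idx] == 0).sum() == 25

    def test_largest_remainder_quotas(self):
        # clusters 10/7/3, target 10 -> 5/4/1 (remainder tie goes to larger cluster)
        y = np.repeat([0, 1, 2], [10, 7, 3])
        idx = stratified_subsample(y, 10, n_iter=1, seed=1)[0]
        counts = np.bincount(y[idx], minlength=3)
        assert list(counts) == [5, 4, 1]

    def test_full_sample_is_identity(self):
        y = np.repeat([0, 1], [6, 4])
        idx = stratified_subsample(y, 10, n_iter=1, seed=2)[0]
        assert np.array_equal(idx, np.arange(10))

    def test_without_replacement(self):
        y = np.repeat([0, 1], 20)
        for idx in stratified_subsample(y, 30, n_iter=10, seed=3):
            assert len(np.unique(idx)) == len(idx)

    def test_target_too_large_rejected(self):
        with pytest.raises(ValidationError):
            stratified_subsample(np.zeros(5, dtype=int), 6)


class TestMetricsUnderSubsampling:
    def test_full_sample_rows_identical(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(8, 1, (20, 2))])
        y = np.repeat([0, 1], 20)
        table = metrics_under_subsampling(X, y, n_target=40, n_iter=3, seed=0)
        assert len(table) == 9
        for _, grp in table.groupby("metric"):
            assert grp["value"].nunique() == 1

    def test_median_silhouette_close_to_full_value(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (100, 2)), rng.normal(6, 1, (100, 2))])
        y = np.repeat([0, 1], 100)
        table = metrics_under_subsampling(X, y, n_target=160, n_iter=50, seed=0)
        med = table[table["metric"] == "silhouette"]["value"].median()
        assert abs(med - silhouette_value(X, y)) < 0.02

    def test_record_bookkeeping(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 2))
        y = np.repeat([0, 1], 15)
        table = metrics_under_subsampling(X, y, n_target=20, n_iter=7, seed=0)
        assert len(table) == 7 * 3
        assert set(table["metric"]) == {"calinski_harabasz", "davies_bouldin", "silhouette"}


def make_metric_table(values: dict, n_iter: int = 4, dataset: str = "ds") -> pd.DataFrame:
    """values: {(version, metric): list of iteration values}."""
    rows = []
    for (version, metric), vals in values.items():
        for it, v in enumerate(vals):
            rows.append(
                {"dataset": dataset, "version": version, "metric": metric,
                 "iteration": it, "value": v}
            )
    return pd.DataFrame(rows)


class TestAggregateRanks:
    def test_single_version_rank_one(self):
        t = make_metric_table({("only", m): [1.0, 2.0] for m in
                               ("silhouette", "calinski_harabasz", "davies_bouldin")})
        out = aggregate_ranks(t)
        assert out.to_dict() == {"only": 1.0}

    def test_dominating_version_gets_1_1(self):
        # v1 better median AND tighter IQR on every cell -> 1 + 0.1*1 = 1.1
        vals = {}
        for m in ("silhouette", "calinski_harabasz"):
            vals[("v1", m)] = [10.0, 10.1, 10.2, 10.3]
            vals[("v2", m)] = [1.0, 2.0, 3.0, 4.0]
        vals[("v1", "davies_bouldin")] = [0.1, 0.11, 0.12, 0.13]
        vals[("v2", "davies_bouldin")] = [1.0, 2.0, 3.0, 4.0]
        out = aggregate_ranks(make_metric_table(vals))
        assert out["v1"] == pytest.approx(1.1)
        assert out["v2"] == pytest.approx(2.2)

    def test_direction_awareness(self):
        # lower davies_bouldin must rank better
        vals = {
            ("v1", "davies_bouldin"): [0.2, 0.2, 0.2, 0.2],
            ("v2", "davies_bouldin"): [0.9, 0.9, 0.9, 0.9],
        }
        out = aggregate_ranks(make_metric_table(vals), metrics=["davies_bouldin"])
        assert out["v1"] < out["v2"]

    def test_median_ties_get_mean_ranks(self):
        vals = {
            ("v1", "silhouette"): [0.5, 0.5, 0.5, 0.5],
            ("v2", "silhouette"): [0.5, 0.5, 0.5, 0.5],
            ("v3", "silhouette"): [0.1, 0.1, 0.1, 0.1],
        }
        out = aggregate_ranks(make_metric_table(vals), metrics=["silhouette"])
        # v1, v2 share performance rank (1+2)/2 = 1.5; all IQRs are 0 so the
        # IQR rank is a three-way mean tie of 2 -> 1.5 + 0.1*2 = 1.7
        assert out["v1"] == pytest.approx(1.7)
        assert out["v2"] == pytest.approx(1.7)
        assert out["v3"] == pytest.approx(3.0 + 0.1 * 2.0)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(9)
        vals = {
            (v, m): list(rng.normal(loc, 1.0, 6))
            for v, loc in (("a", 0.0), ("b", 1.0), ("c", 2.0))
            for m in ("silhouette", "calinski_harabasz", "davies_bouldin")
        }
        t1 = make_metric_table(vals)
        t2 = t1.copy()
        t2["value"] = 3.5 * t2["value"] + 11.0
        pd.testing.assert_series_equal(aggregate_ranks(t1), aggregate_ranks(t2))

    def test_missing_cell_rejected(self):
        t = make_metric_table(
            {("v1", "silhouette"): [1.0], ("v2", "silhouette"): [0.5],
             ("v1", "davies_bouldin"): [0.1]}
        )
        with pytest.raises(ValidationError):
            aggregate_ranks(t)


class TestCorrespondence:
    def test_identical_assignments(self):
        a = assignment([0, 0, 1, 1, 2, 2])
        c = cluster_correspondence(a, a)
        assert np.array_equal(np.diag(c.jaccard.to_numpy()), [1.0, 1.0, 1.0])
        assert c.jaccard.to_numpy().sum() == pytest.approx(3.0)

    def test_renamed_labels_give_permutation(self):
        ids = [f"d{i}" for i in range(6)]
        pre = assignment([0, 0, 1, 1, 2, 2], ids)
        post = assignment([2, 2, 0, 0, 1, 1], ids)
        j = cluster_correspondence(pre, post).jaccard
        assert sorted(j.to_numpy().max(axis=1)) == [1.0, 1.0, 1.0]
        assert j.to_numpy().sum() == pytest.approx(3.0)

    def test_merge_hand_arithmetic(self):
        # pre: A={d0..d3}, B={d4..d7}; post moves d4,d5 into A's cluster
        ids = [f"d{i}" for i in range(8)]
        pre = assignment([0, 0, 0, 0, 1, 1, 1, 1], ids)
        post = assignment([0, 0, 0, 0, 0, 0, 1, 1], ids)
        c = cluster_correspondence(pre, post)
        assert c.counts.loc[0, 0] == 4 and c.counts.loc[0, 1] == 2
        assert c.counts.loc[1, 1] == 2 and c.counts.loc[1, 0] == 0
        assert c.jaccard.loc[0, 0] == pytest.approx(4 / 6)
        assert c.jaccard.loc[0, 1] == pytest.approx(2 / 8)
        assert c.jaccard.loc[1, 1] == pytest.approx(2 / 4)

    def test_marginals_match_cluster_sizes(self):
        rng = np.random.default_rng(10)
        ids = [f"d{i}" for i in range(60)]
        pre = assignment(rng.integers(0, 3, 60), ids)
        keep = ids[:45]
        post_labels = pd.Series(rng.integers(0, 2, 45), index=keep)
        post = ClusterAssignment(labels=post_labels, provenance="post")
        c = cluster_correspondence(pre, post)
        assert c.counts.to_numpy().sum() == 45
        assert list(c.counts.sum(axis=1)) == list(post.labels.value_counts().sort_index())

    def test_disjoint_universes_rejected(self):
        a = assignment([0, 1], ["a", "b"])
        b = assignment([0, 1], ["c", "d"])
        with pytest.raises(ValidationError):
            cluster_correspondence(a, b)


def test_removing_heterotypic_multiplets_improves_silhouette(two_type_sim):
    """Truth-flag removal of heterotypic multiplets raises median silhouette."""
    _, truth, _, counts = two_type_sim
    # coarse resolution: one community per transcriptional population
    emb_all, asg_all = preprocess_and_cluster(counts, n_hvg=200, resolution=0.3, seed=1)
    keep = ~counts.obs["is_heterotypic"].to_numpy()
    cleaned = counts[keep].copy()
    emb_cl, asg_cl = preprocess_and_cluster(cleaned, n_hvg=200, resolution=0.3, seed=1)
    n_target = (min(counts.n_obs, cleaned.n_obs) - 1) // 100 * 100
    med = {}
    for name, (e, a) in (("all", (emb_all, asg_all)), ("clean", (emb_cl, asg_cl))):
        t = metrics_under_subsampling(e, a, n_target=n_target, n_iter=30, seed=2,
                                      version=name)
        med[name] = t[t["metric"] == "silhouette"]["value"].median()
    assert med["clean"] > med["all"]
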