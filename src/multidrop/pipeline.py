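"""End-to-end pipeline: simulate/ingest -> estimate rates -> score/call ->
remove -> cluster -> evaluate -> DGE compare.

Each stage writes its outputs under ``outdir`` and the run ends with a JSON
manifest recording parameters, seeds, and every summary number, so a rerun
with the same configuration reproduces the manifest byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, detection, dge, io, occupancy, simulate
from .errors import ValidationError

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("multidrop")


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    With ``matrix_dir``/``truth_path`` unset the pipeline simulates its own
    dataset from the simulation parameters; otherwise it ingests the given
    matrix and truth/hashing table.  ``score_dir`` may hold per-method score
    CSVs; a built-in library-size baseline score is always evaluated.
    """

    outdir: str = "multidrop_run"
    matrix_dir: str | None = None
    truth_path: str | None = None
    score_dir: str | None = None
    # simulation parameters (used when no matrix is given)
    lambda_occupancy: float = 0.7
    n_samples: int = 2
    n_droplets_total: int = 6000
    n_genes: int = 400
    cell_types: tuple[tuple[str, float], ...] = (
        ("typeA", 0.4),
        ("typeB", 0.4),
        ("typeC", 0.2),
    )
    mean_library_size: float = 2000.0
    dispersion: float = 2.0
    # analysis parameters
    chemistry: str = "3p_v3"
    rate_per_1000: float = 0.8
    n_hvg: int = 2000
    n_pcs: int = 10
    n_iter: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "cell_types" in raw:
            raw["cell_types"] = tuple((str(n), float(p)) for n, p in raw["cell_types"])
        return cls(**raw)


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return (and write) the result manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _round_floats(asdict(config))}

    # --- stage 1: simulate or ingest -------------------------------------
    if config.matrix_dir is None:
        logger.info("[simulate] drawing synthetic dataset")
        sim = simulate.SimulationConfig(
            lambda_occupancy=config.lambda_occupancy,
            n_samples=config.n_samples,
            n_droplets_total=config.n_droplets_total,
            cell_types=config.cell_types,
            n_genes=config.n_genes,
            mean_library_size=config.mean_library_size,
            dispersion=config.dispersion,
            seed=config.seed,
        )
        truth = simulate.simulate_encapsulation(sim)
        panel = simulate.make_gene_panel(sim.n_genes, sim.type_names, seed=config.seed)
        counts = simulate.simulate_expression(truth, panel, sim)
        io.write_counts_mtx(counts, outdir / "matrix")
        io.write_truth_tsv(truth, outdir / "truth.tsv")
        labels = simulate.hashing_labels(truth)
    else:
        logger.info("[ingest] reading %s", config.matrix_dir)
        if not Path(config.matrix_dir).exists():
            raise ValidationError(f"matrix_dir does not exist: {config.matrix_dir}")
        if config.truth_path is None or not Path(config.truth_path).exists():
            raise ValidationError("truth_path must point to an existing truth/label TSV")
        counts = io.read_counts_mtx(config.matrix_dir)
        truth = io.read_truth_tsv(config.truth_path)
        labels = simulate.hashing_labels(truth).reindex(counts.obs_names)
        if labels.isna().any():
            raise ValidationError("truth table does not cover all matrix droplets")
        counts.obs["hashing_label"] = labels.to_numpy()

    n = counts.n_obs
    manifest["n_droplets"] = int(n)

    # --- stage 2: rate estimation ----------------------------------------
    logger.info("[estimate] occupancy model")
    f_obs = occupancy.observed_intersample_rate(labels)
    sol = occupancy.estimate_true_rate(f_obs, config.n_samples)
    chem = occupancy.ChemistryHeuristic(config.chemistry, config.rate_per_1000)
    heuristic = occupancy.heuristic_rate(n, chem)
    manifest["rates"] = _round_floats(
        {
            "f_obs": f_obs,
            "lambda_hat": sol.lambda_hat,
            "f_diff": sol.f_diff,
            "f_mult": sol.f_mult,
            "heuristic": heuristic,
        }
    )

    # --- stage 3: scores, accuracy, calling -------------------------------
    logger.info("[score] evaluating multiplet scores")
    total_umi = np.asarray(counts.X.sum(axis=1)).ravel()
    scoresets = [
        detection.ScoreSet(
            method="library_size",
            scores=pd.Series(total_umi.astype(float), index=counts.obs_names),
        )
    ]
    if config.score_dir is not None:
        for p in sorted(Path(config.score_dir).glob("*.csv")):
            scoresets.append(io.read_scores_csv(p))
    accuracy = {}
    calls = {}
    for ss in scoresets:
        accuracy[ss.method] = {
            "auprc": detection.auprc(ss, labels),
            "auroc": detection.auroc(ss, labels),
        }
        calls[ss.method] = detection.call_multiplets_at_rate(ss, heuristic)
    hash_ids = frozenset(counts.obs_names[labels.to_numpy(dtype=bool)])
    inter = detection.intersection_counts(
        {m: set(c.called) for m, c in calls.items()} | {"cell_hashing": set(hash_ids)}
    )
    manifest["detection"] = _round_floats(accuracy)
    manifest["intersections"] = [["+".join(p), c] for p, c in inter]

    # --- stage 4: removal + clustering ------------------------------------
    logger.info("[cluster] building dataset versions")
    versions = {"no_processing": counts}
    versions["cell_hashing"] = detection.remove_called(
        counts, detection.CallSet("cell_hashing", hash_ids, f_obs)
    )
    for m, c in calls.items():
        versions[m] = detection.remove_called(counts, c)

    embeddings, assignments = {}, {}
    for name, adata in versions.items():
        embeddings[name], assignments[name] = clustering.preprocess_and_cluster(
            adata, n_hvg=config.n_hvg, n_pcs=config.n_pcs, seed=config.seed, provenance=name
        )
    manifest["n_clusters"] = {name: a.n_clusters for name, a in assignments.items()}

    # --- stage 5: clustering quality under subsampling --------------------
    logger.info("[evaluate] metrics under stratified subsampling")
    smallest = min(v.n_obs for v in versions.values())
    n_target = (smallest - 1) // 100 * 100  # largest multiple of 100 strictly below
    if n_target < 100:
        raise ValidationError(f"smallest version too small for subsampling ({smallest})")
    tables = [
        clustering.metrics_under_subsampling(
            embeddings[name],
            assignments[name],
            n_target=n_target,
            n_iter=config.n_iter,
            seed=config.seed,
            dataset="run",
            version=name,
        )
        for name in versions
    ]
    metric_table = pd.concat(tables, ignore_index=True)
    metric_table.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    ranks = clustering.aggregate_ranks(metric_table)
    ranks_sil = clustering.aggregate_ranks(metric_table, metrics=["silhouette"])
    manifest["subsampling"] = {"n_target": int(n_target), "n_iter": int(config.n_iter)}
    manifest["average_rank"] = _round_floats(ranks.to_dict())
    manifest["average_rank_silhouette"] = _round_floats(ranks_sil.to_dict())

    # --- stage 6: cluster correspondence ----------------------------------
    corr = clustering.cluster_correspondence(
        assignments["no_processing"], assignments["cell_hashing"]
    )
    corr.counts.to_csv(outdir / "correspondence_counts.tsv", sep="\t")
    corr.jaccard.round(4).to_csv(outdir / "correspondence_jaccard.tsv", sep="\t")
    manifest["correspondence_max_jaccard"] = _round_floats(
        corr.jaccard.max(axis=1).to_dict()
    )

    # --- stage 7: DGE stability -------------------------------------------
    logger.info("[dge] comparing cluster-pair contrasts with/without multiplets")
    base = assignments["no_processing"].labels
    sizes = base.value_counts()
    if len(sizes) >= 2:
        c0, c1 = int(sizes.index[0]), int(sizes.index[1])
        ids_a = list(base.index[base == c0])
        ids_b = list(base.index[base == c1])
        genes = dge.filter_genes(counts)
        run1 = dge.de_test(counts, ids_a, ids_b, genes=genes)
        keep = ~labels.astype(bool)
        ids_a2 = [d for d in ids_a if keep.loc[d]]
        ids_b2 = [d for d in ids_b if keep.loc[d]]
        run2 = dge.de_test(counts, ids_a2, ids_b2, genes=genes)
        run1.to_csv(outdir / "dge_all.tsv", sep="\t")
        run2.to_csv(outdir / "dge_demultipleted.tsv", sep="\t")
        summary = dge.compare_de_runs(run1, run2)
        manifest["dge"] = _round_floats(
            {
                "cluster_pair": [c0, c1],
                "jaccard": summary.jaccard,
                "spearman": summary.spearman,
                "n_union": summary.n_union,
            }
        )
    else:
        manifest["dge"] = None

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    logger.info("[done] manifest written to %s", outdir / "manifest.json")
    return manifest
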