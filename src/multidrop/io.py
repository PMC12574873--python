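"""Readers and writers for the package's on-disk formats.

Count matrices use the CellRanger-style layout: ``matrix.mtx`` (MatrixMarket
coordinate, genes x droplets) with ``barcodes.tsv`` and ``features.tsv``
alongside.  Droplet truth tables and hashing labels are TSV; per-method
multiplet scores are two-column CSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .detection import ScoreSet
from .errors import FormatError, ValidationError
from .simulate import DropletTable, hashing_labels

__all__ = [
    "read_counts_mtx",
    "write_counts_mtx",
    "read_truth_tsv",
    "write_truth_tsv",
    "read_scores_csv",
    "read_labels_tsv",
]

logger = logging.getLogger("multidrop")

TRUTH_COLUMNS = [
    "droplet_id",
    "k",
    "sample_ids",
    "type_ids",
    "is_multiplet",
    "is_intersample",
    "hashing_label",
]


def write_counts_mtx(counts: ad.AnnData, outdir: str | Path) -> None:
    """Write droplets x genes counts as matrix.mtx + barcodes.tsv + features.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = counts.X if sp.issparse(counts.X) else sp.csr_matrix(counts.X)
    scipy.io.mmwrite(outdir / "matrix.mtx", X.T.astype(np.int64), field="integer")
    pd.Series(counts.obs_names).to_csv(outdir / "barcodes.tsv", index=False, header=False)
    feats = pd.DataFrame(
        {"gene_id": counts.var_names, "gene_name": counts.var_names, "type": "Gene Expression"}
    )
    feats.to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)


def read_counts_mtx(indir: str | Path) -> ad.AnnData:
    """Read a matrix.mtx + barcodes.tsv + features.tsv directory into AnnData."""
    indir = Path(indir)
    for name in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
        if not (indir / name).exists():
            raise FormatError(f"missing {name} in {indir}")
    try:
        M = scipy.io.mmread(indir / "matrix.mtx")
    except ValueError as exc:
        raise FormatError(f"malformed MatrixMarket file: {exc}") from exc
    barcodes = pd.read_csv(indir / "barcodes.tsv", header=None, sep="\t")[0].astype(str)
    features = pd.read_csv(indir / "features.tsv", header=None, sep="\t")
    if M.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"matrix is {M.shape} but features/barcodes give ({len(features)}, {len(barcodes)})"
        )
    X = sp.csr_matrix(M.T).astype(np.int64)
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="droplet_id")),
        var=pd.DataFrame(index=pd.Index(features[0].astype(str), name="gene_id")),
    )


def write_truth_tsv(table: DropletTable, path: str | Path) -> None:
    """Write the per-droplet truth table (member ids comma-joined)."""
    k = table.droplets["k"].to_numpy()
    ends = np.cumsum(k)
    starts = ends - k
    samples = np.array(table.sample_names, dtype=object)[table.cell_sample]
    types = np.array(table.type_names, dtype=object)[table.cell_type]
    df = pd.DataFrame(
        {
            "droplet_id": table.droplets.index,
            "k": k,
            "sample_ids": [",".join(samples[s:e]) for s, e in zip(starts, ends)],
            "type_ids": [",".join(types[s:e]) for s, e in zip(starts, ends)],
            "is_multiplet": table.droplets["is_multiplet"].to_numpy(),
            "is_intersample": table.droplets["is_intersample"].to_numpy(),
            "hashing_label": np.where(hashing_labels(table), "multiplet", "singlet"),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> DropletTable:
    """Reconstruct a DropletTable from the TSV written by :func:`write_truth_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(TRUTH_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise FormatError(f"truth table missing columns: {sorted(missing)}")
    extra = set(df.columns) - set(TRUTH_COLUMNS)
    if extra:
        logger.warning("truth table: ignoring unknown columns %s", sorted(extra))
    if df.empty:
        raise ValidationError("truth table has no droplets")
    k = df["k"].astype(int).to_numpy()
    sample_lists = [s.split(",") for s in df["sample_ids"]]
    type_lists = [s.split(",") for s in df["type_ids"]]
    if any(len(s) != kk or len(t) != kk for s, t, kk in zip(sample_lists, type_lists, k)):
        raise FormatError("member list lengths disagree with k")
    sample_names = sorted({s for lst in sample_lists for s in lst})
    type_names = sorted({t for lst in type_lists for t in lst})
    s_code = {s: i for i, s in enumerate(sample_names)}
    t_code = {t: i for i, t in enumerate(type_names)}
    cell_droplet = np.repeat(np.arange(len(df)), k)
    cell_sample = np.array([s_code[s] for lst in sample_lists for s in lst])
    cell_type = np.array([t_code[t] for lst in type_lists for t in lst])
    droplets = pd.DataFrame(
        {
            "k": k,
            "is_multiplet": df["is_multiplet"].map({"True": True, "False": False}).to_numpy(),
            "is_intersample": df["is_intersample"].map({"True": True, "False": False}).to_numpy(),
        },
        index=pd.Index(df["droplet_id"], name="droplet_id"),
    )
    starts = np.concatenate([[0], np.cumsum(k)[:-1]])
    droplets["is_heterotypic"] = (
        np.maximum.reduceat(cell_type, starts) != np.minimum.reduceat(cell_type, starts)
    ) if len(cell_type) else False
    return DropletTable(
        droplets=droplets,
        cell_droplet=cell_droplet,
        cell_sample=cell_sample,
        cell_type=cell_type,
        sample_names=sample_names,
        type_names=type_names,
    )


def read_labels_tsv(path: str | Path) -> pd.Series:
    """Read a (droplet_id, hashing_label) TSV into a boolean label series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"droplet_id", "hashing_label"} <= set(df.columns):
        raise FormatError("label file needs columns droplet_id, hashing_label")
    labels = df["hashing_label"].map({"multiplet": True, "singlet": False})
    if labels.isna().any():
        bad = df.loc[labels.isna(), "hashing_label"].iloc[0]
        raise FormatError(f"unrecognized hashing label {bad!r}")
    return pd.Series(labels.to_numpy(), index=pd.Index(df["droplet_id"], name="droplet_id"))


def read_scores_csv(path: str | Path, method: str | None = None) -> ScoreSet:
    """Read a per-method score file (CSV header ``droplet_id,score``).

    The method name defaults to the file stem.  A header-only file yields an
    empty score set; a non-numeric score is an error naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if not {"droplet_id", "score"} <= set(df.columns):
        raise FormatError(f"{path.name}: score file needs columns droplet_id, score")
    extra = set(df.columns) - {"droplet_id", "score"}
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path.name, sorted(extra))
    scores = pd.to_numeric(df["score"], errors="coerce")
    if scores.isna().any():
        row = int(np.flatnonzero(scores.isna())[0])
        raise FormatError(
            f"{path.name}: non-numeric score {df['score'].iloc[row]!r} at data row {row + 1}"
        )
    return ScoreSet(
        method=method or path.stem,
        scores=pd.Series(
            scores.to_numpy(dtype=float), index=pd.Index(df["droplet_id"], name="droplet_id")
        ),
    )
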