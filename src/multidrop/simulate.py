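"""Synthetic droplet encapsulation with cell hashing and summed multiplet expression.

The generator reproduces the statistical structure the occupancy model and the
downstream evaluation protocols assume: droplets receive ``k ~ Poisson(lam)``
cells (empties are then discarded), each cell is independently assigned one of
``D`` hashed samples and one of several transcriptional types, and a droplet's
expression profile is the elementwise sum of its member cells' counts.  Cell
hashing flags exactly the droplets whose members span two or more samples, so
the hashing label is a lower bound on true multiplet status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError

__all__ = [
    "SimulationConfig",
    "DropletTable",
    "GenePanel",
    "simulate_encapsulation",
    "make_gene_panel",
    "simulate_expression",
    "hashing_labels",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic encapsulation experiment.

    ``lambda_occupancy`` is the mean number of cells per droplet including
    empties; ``n_droplets_total`` droplets are drawn before empties are
    discarded.  ``dispersion`` is the negative-binomial shape (var =
    mu + mu^2/dispersion); ``inf`` gives the Poisson limit.
    """

    lambda_occupancy: float = 0.7
    n_samples: int = 2
    sample_props: tuple[float, ...] | None = None
    n_droplets_total: int = 20_000
    cell_types: tuple[tuple[str, float], ...] = (("typeA", 0.5), ("typeB", 0.5))
    n_genes: int = 400
    mean_library_size: float = 2_000.0
    dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lambda_occupancy > 0:
            raise ValidationError("lambda_occupancy must be > 0")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.n_droplets_total <= 0:
            raise ValidationError("n_droplets_total must be > 0")
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be > 0")
        if not self.mean_library_size > 0:
            raise ValidationError("mean_library_size must be > 0")
        if not self.dispersion > 0:
            raise ValidationError("dispersion must be > 0 (inf for Poisson)")
        if len(self.cell_types) == 0:
            raise ValidationError("cell_types must be nonempty")
        props = np.array([p for _, p in self.cell_types], dtype=float)
        if abs(props.sum() - 1.0) > 1e-12 or (props < 0).any():
            raise ValidationError("cell type proportions must be nonnegative and sum to 1")
        if self.sample_props is not None:
            sprops = np.asarray(self.sample_props, dtype=float)
            if len(sprops) != self.n_samples:
                raise ValidationError("sample_props length must equal n_samples")
            if abs(sprops.sum() - 1.0) > 1e-12 or (sprops < 0).any():
                raise ValidationError("sample_props must be nonnegative and sum to 1")

    @property
    def resolved_sample_props(self) -> np.ndarray:
        if self.sample_props is None:
            return np.full(self.n_samples, 1.0 / self.n_samples)
        return np.asarray(self.sample_props, dtype=float)

    @property
    def type_names(self) -> list[str]:
        return [name for name, _ in self.cell_types]

    @property
    def type_props(self) -> np.ndarray:
        return np.array([p for _, p in self.cell_types], dtype=float)


@dataclass
class DropletTable:
    """Per-droplet ground truth for a simulated (or ingested) experiment.

    ``droplets`` is indexed by droplet barcode with columns ``k`` (member cell
    count), ``is_multiplet`` (k >= 2), ``is_intersample`` (members span >= 2
    samples) and ``is_heterotypic`` (members span >= 2 cell types).  Member
    cells are stored columnarly: ``cell_droplet[i]`` is the positional row of
    cell ``i``'s droplet, with sample/type integer codes alongside.
    """

    droplets: pd.DataFrame
    cell_droplet: np.ndarray
    cell_sample: np.ndarray
    cell_type: np.ndarray
    sample_names: list[str] = field(default_factory=list)
    type_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.droplets) == 0:
            raise ValidationError("droplet table must be nonempty")
        if not self.droplets.index.is_unique:
            raise ValidationError("droplet ids must be unique")
        if (self.droplets["k"] < 1).any():
            raise ValidationError("empty droplets must not be retained")
        if (self.droplets["is_intersample"] & ~self.droplets["is_multiplet"]).any():
            raise ValidationError("is_intersample implies is_multiplet")

    def __len__(self) -> int:
        return len(self.droplets)

    @property
    def droplet_ids(self) -> pd.Index:
        return self.droplets.index

    def members(self, droplet_id: str) -> list[tuple[str, str]]:
        """List of (sample id, cell type id) for one droplet."""
        pos = self.droplets.index.get_loc(droplet_id)
        sel = self.cell_droplet == pos
        return [
            (self.sample_names[s], self.type_names[t])
            for s, t in zip(self.cell_sample[sel], self.cell_type[sel])
        ]


@dataclass(frozen=True)
class GenePanel:
    """Per-type mean expression rates with disjoint marker blocks.

    ``means`` is genes x types (relative rates, rescaled to the configured
    library size at sampling time); ``marker_blocks`` maps each type to the
    positional indices of its elevated marker genes.
    """

    gene_ids: tuple[str, ...]
    means: pd.DataFrame
    marker_blocks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if (self.means.values < 0).any():
            raise ValidationError("expression rates must be nonnegative")
        seen: set[int] = set()
        for t, block in self.marker_blocks.items():
            if len(block) == 0:
                raise ValidationError(f"marker block for {t} is empty")
            if seen & set(block.tolist()):
                raise ValidationError("marker blocks must be disjoint")
            seen |= set(block.tolist())


def _barcodes(n: int, rng: np.random.Generator, width: int = 14) -> np.ndarray:
    codes = rng.integers(0, 4, size=(n, width))
    bc = np.array(["".join(row) for row in _BASES[codes]])
    # regenerate any colliding barcodes deterministically
    while len(np.unique(bc)) < n:  # pragma: no cover - 4^14 >> n in practice
        _, idx, counts = np.unique(bc, return_index=True, return_counts=True)
        dup = np.setdiff1d(np.arange(n), idx[counts == 1], assume_unique=False)
        codes[dup] = rng.integers(0, 4, size=(len(dup), width))
        bc = np.array(["".join(row) for row in _BASES[codes]])
    return bc


def simulate_encapsulation(config: SimulationConfig) -> DropletTable:
    """Draw droplets at Poisson occupancy and assign each cell a sample and type.

    ``n_droplets_total`` droplets receive ``k ~ Poisson(lambda_occupancy)``
    cells; droplets with k = 0 are discarded.  Cells are assigned samples and
    types i.i.d. (no co-encapsulation bias).
    """
    rng = np.random.default_rng(config.seed)
    k_all = rng.poisson(config.lambda_occupancy, size=config.n_droplets_total)
    k = k_all[k_all > 0]
    n = k.size
    if n == 0:
        raise ValidationError(
            "no non-empty droplets drawn; increase n_droplets_total or lambda_occupancy"
        )
    total_cells = int(k.sum())
    cell_droplet = np.repeat(np.arange(n), k)
    cell_sample = rng.choice(config.n_samples, size=total_cells, p=config.resolved_sample_props)
    cell_type = rng.choice(len(config.cell_types), size=total_cells, p=config.type_props)

    starts = np.concatenate([[0], np.cumsum(k)[:-1]])
    s_span = np.maximum.reduceat(cell_sample, starts) != np.minimum.reduceat(cell_sample, starts)
    t_span = np.maximum.reduceat(cell_type, starts) != np.minimum.reduceat(cell_type, starts)

    droplets = pd.DataFrame(
        {
            "k": k,
            "is_multiplet": k >= 2,
            "is_intersample": s_span,
            "is_heterotypic": t_span,
        },
        index=pd.Index(_barcodes(n, rng), name="droplet_id"),
    )
    return DropletTable(
        droplets=droplets,
        cell_droplet=cell_droplet,
        cell_sample=cell_sample,
        cell_type=cell_type,
        sample_names=[f"sample{i + 1}" for i in range(config.n_samples)],
        type_names=config.type_names,
    )


def make_gene_panel(
    n_genes: int,
    cell_types: Sequence[str],
    seed: int,
    marker_block_size: int = 10,
    marker_fold: float = 8.0,
) -> GenePanel:
    """Build per-type mean rate vectors sharing a heavy-tailed baseline.

    All types share a log-normal baseline; each type's disjoint marker block
    (``marker_block_size`` genes) is elevated ``marker_fold``-fold, so type
    mean vectors differ exactly at marker positions.
    """
    cell_types = list(cell_types)
    if n_genes < 10 * len(cell_types):
        raise ValidationError(
            f"n_genes={n_genes} too small: need >= 10 genes per type ({len(cell_types)} types)"
        )
    if marker_block_size * len(cell_types) > n_genes:
        raise ValidationError("marker blocks exceed the gene panel")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    gene_ids = tuple(f"gene{i:05d}" for i in range(n_genes))
    means = pd.DataFrame(
        np.tile(base[:, None], (1, len(cell_types))), index=list(gene_ids), columns=cell_types
    )
    blocks: dict[str, np.ndarray] = {}
    for i, t in enumerate(cell_types):
        block = np.arange(i * marker_block_size, (i + 1) * marker_block_size)
        means.iloc[block, i] *= marker_fold
        blocks[t] = block
    return GenePanel(gene_ids=gene_ids, means=means, marker_blocks=blocks)


def simulate_expression(
    droplets: DropletTable, panel: GenePanel, config: SimulationConfig
) -> ad.AnnData:
    """Draw per-cell counts and sum them within droplets.

    Each cell's counts are negative binomial per gene, with its type's rate
    vector scaled so the expected per-cell total equals ``mean_library_size``
    (``dispersion=inf`` gives Poisson counts).  A droplet's row is the sum of
    its member cells' rows, so a k-cell droplet has expected total
    ``k * mean_library_size``.
    """
    missing = set(droplets.type_names) - set(panel.means.columns)
    if missing:
        raise ValidationError(f"gene panel lacks cell types: {sorted(missing)}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_cells = len(droplets.cell_droplet)
    n_genes = len(panel.gene_ids)
    counts = np.empty((n_cells, n_genes), dtype=np.int64)
    for ti, tname in enumerate(droplets.type_names):
        sel = droplets.cell_type == ti
        if not sel.any():
            continue
        rates = panel.means[tname].to_numpy()
        mu = rates / rates.sum() * config.mean_library_size
        shape = (int(sel.sum()), n_genes)
        if np.isinf(config.dispersion):
            counts[sel] = rng.poisson(np.broadcast_to(mu, shape))
        else:
            lam = rng.gamma(config.dispersion, mu / config.dispersion, size=shape)
            counts[sel] = rng.poisson(lam)

    n_drop = len(droplets)
    agg = sp.csr_matrix(
        (np.ones(n_cells), (droplets.cell_droplet, np.arange(n_cells))),
        shape=(n_drop, n_cells),
    )
    X = sp.csr_matrix(agg @ counts).astype(np.int64)
    adata = ad.AnnData(
        X=X,
        obs=droplets.droplets.copy(),
        var=pd.DataFrame(index=pd.Index(list(panel.gene_ids), name="gene_id")),
    )
    adata.obs["hashing_label"] = hashing_labels(droplets).to_numpy()
    return adata


def hashing_labels(droplets: DropletTable) -> pd.Series:
    """Boolean hashing label per droplet: True iff members span >= 2 samples.

    Intra-sample multiplets and singlets are both labelled False — hashing is
    a lower bound on true multiplet status.
    """
    return droplets.droplets["is_intersample"].rename("hashing_label").astype(bool)
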