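import numpy as np
import pandas as pd
import pytest

from multidrop import (
    ScoreSet,
    SimulationConfig,
    make_gene_panel,
    simulate_encapsulation,
    simulate_expression,
)


def make_scoreset(values, ids=None, method="m"):
    ids = ids if ids is not None else [f"d{i:03d}" for i in range(len(values))]
    return ScoreSet(method=method, scores=pd.Series(np.asarray(values, float), index=ids))


@pytest.fixture(scope="session")
def two_type_sim():
    """Two well-separated cell types at moderate occupancy, with ground truth."""
    cfg = SimulationConfig(
        lambda_occupancy=0.7,
        n_samples=2,
        n_droplets_total=1200,
        cell_types=(("typeA", 0.5), ("typeB", 0.5)),
        n_genes=300,
        mean_library_size=2000.0,
        dispersion=2.0,
        seed=7,
    )
    truth = simulate_encapsulation(cfg)
    panel = make_gene_panel(cfg.n_genes, cfg.type_names, seed=7, marker_block_size=20)
    counts = simulate_expression(truth, panel, cfg)
    return cfg, truth, panel, counts
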