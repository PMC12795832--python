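import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cellplast import CountMatrixPair, SimConfig, simulate_tree

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_pair(spliced, unspliced=None, genes=None, cells=None) -> CountMatrixPair:
    """Small helper: build a CountMatrixPair from dense arrays with default ids."""
    spliced = np.asarray(spliced)
    if unspliced is None:
        unspliced = np.zeros_like(spliced)
    n_cells, n_genes = spliced.shape
    return CountMatrixPair(
        spliced=spliced,
        unspliced=np.asarray(unspliced),
        gene_ids=genes if genes is not None else [f"g{j}" for j in range(n_genes)],
        cell_ids=cells if cells is not None else [f"c{i}" for i in range(n_cells)],
    )


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated dataset shared by read-only tests."""
    cfg = SimConfig(seed=11, n_genes=300, cells_per_cluster=60)
    counts, cells, degrees, truth = simulate_tree(cfg)
    return cfg, counts, cells, degrees, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
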