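import numpy as np
import pytest

import dsbench as d


@pytest.fixture(scope="session")
def small_dataset():
    """Small two-condition dataset with DE genes and moderate subject effect."""
    cfg = d.SimConfig(
        n_samples_total=8,
        avg_cells_per_sample=60,
        n_genes=150,
        n_de_genes=15,
        cell_overdispersion=0.2,
        sample_overdispersion=1.0,
        seed=11,
    )
    return d.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_iid_dataset():
    """Null data with negligible subject effect (cells effectively iid)."""
    cfg = d.SimConfig(
        n_samples_total=10,
        avg_cells_per_sample=60,
        n_genes=2000,
        n_de_genes=0,
        cell_overdispersion=0.2,
        sample_overdispersion=1e6,
        seed=21,
    )
    return d.simulate_dataset(cfg)[0]


@pytest.fixture(scope="session")
def null_hier_dataset():
    """Null data with strong subject effects (pseudoreplication regime)."""
    cfg = d.SimConfig(
        n_samples_total=10,
        avg_cells_per_sample=60,
        n_genes=2000,
        n_de_genes=0,
        cell_overdispersion=0.2,
        sample_overdispersion=0.1,
        seed=22,
    )
    return d.simulate_dataset(cfg)[0]


@pytest.fixture()
def tiny_matrix():
    """Hand-built 3-gene x 4-cell matrix, two samples per condition side."""
    return d.CellCountMatrix(
        counts=np.array([[1, 2, 3, 4], [0, 0, 5, 5], [2, 2, 2, 2]]),
        gene_ids=["g1", "g2", "g3"],
        cell_ids=["c1", "c2", "c3", "c4"],
        cell_to_sample=np.array(["s1", "s1", "s2", "s2"], dtype=object),
        sample_to_condition={"s1": "A", "s2": "B"},
    )
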