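import numpy as np
import pandas as pd
import pytest

from nichescreen import ExpressionMatrix, SimConfig, simulate_dataset
from nichescreen.simulate import PlantedCircuit


@pytest.fixture(scope="session")
def default_sim():
    """The canonical study conditions: 3 lineages x 50 cells, 2000 genes,
    six planted circuits (PE->EPI IGF motif first), 20 decoys, seed 0."""
    config = SimConfig(seed=0)
    matrix, lengths, truth = simulate_dataset(config)
    return config, matrix, lengths, truth


@pytest.fixture()
def small_sim_config():
    """Factory for a scaled-down simulation (fast property tests)."""

    def make(**overrides):
        base = dict(
            n_genes=300,
            cells_per_lineage={"EPI": 15, "PE": 15, "TE": 15},
            planted_pairs=[PlantedCircuit("IGF1", "IGF1R", "PE", "EPI")],
            n_decoy_pairs=3,
            n_planted_hvgs=0,
            planted_gene_sets=[],
            library_size=100_000,
            seed=0,
        )
        base.update(overrides)
        return SimConfig(**base)

    return make


def make_matrix(values, lineages, scale="counts", genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    cells = cells or [f"c{j}" for j in range(n_cells)]
    frame = pd.DataFrame(values, index=genes, columns=cells)
    ann = pd.DataFrame({"lineage": lineages}, index=cells)
    return ExpressionMatrix(frame, ann, scale)


@pytest.fixture()
def matrix_factory():
    return make_matrix
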