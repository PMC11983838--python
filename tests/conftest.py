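import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from highmt import CellTable, SynthConfig, simulate_cohort


def make_table(counts, patients=None, compartments=None, cell_types=None,
               gene_ids=None, **extra_meta) -> CellTable:
    """Tiny dense-counts CellTable builder for hand-crafted fixtures."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    cell_ids = [f"c{i}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "patient_id": patients or ["P0"] * n_cells,
            "compartment": compartments or ["malignant"] * n_cells,
            "cell_type": cell_types or ["tumor"] * n_cells,
            **extra_meta,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return CellTable(
        counts=sp.csr_matrix(counts),
        gene_ids=pd.Index(gene_ids or [f"g{j}" for j in range(n_genes)]),
        cell_ids=pd.Index(cell_ids),
        cell_meta=meta,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    cfg = SynthConfig(
        n_patients=3, cells_per_patient=120, n_genes=400, seed=42,
        stress_effect=0.8,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
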